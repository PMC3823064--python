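"""Build a complete synthetic input bundle on disk for pipeline tests and
the acceptance script."""

from pathlib import Path

import pandas as pd
import yaml

from specswap import (
    KineticDataset,
    KineticsSpec,
    MsaSpec,
    RateLawParams,
    StructureSpec,
    TreeSpec,
    fig3_like_tree,
    simulate_kinetics,
    simulate_msa,
    simulate_structure,
    write_alignment,
    write_kinetic_table,
    write_leaf_states,
    write_structure,
    write_tree,
)

N_COLUMNS = 60


def build_bundle(out_dir: Path, seed: int = 0, n_perm: int = 2000) -> Path:
    """Write alignment, structure, kinetics, tree, annotations and a YAML
    config; returns the config path."""
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_seed = seed

    msa = simulate_msa(
        MsaSpec(n_sequences=30, n_columns=N_COLUMNS, modal_fractions=0.5, gap_probability=0.05, seed=rng_seed)
    )
    write_alignment(msa, out_dir / "alignment.fasta")

    distances = [2.0 + (i * 28.0 / (N_COLUMNS - 1)) for i in range(N_COLUMNS)]
    model, _ = simulate_structure(
        StructureSpec(planted_distances=tuple(distances), seed=rng_seed)
    )
    write_structure(model, out_dir / "structure.pdb")

    frames = []
    for enzyme, truth in [
        ("AspPreferring", RateLawParams(kcat=100.0, Km_AA=2.0, Km_cosub=0.5)),
        ("PhePreferring", RateLawParams(kcat=80.0, Km_AA=8.0, Km_cosub=0.5)),
    ]:
        for substrate, km_scale in [("Asp", 1.0), ("Phe", 5.0 if enzyme == "AspPreferring" else 0.05)]:
            truth_s = RateLawParams(
                kcat=truth.kcat, Km_AA=truth.Km_AA * km_scale, Km_cosub=truth.Km_cosub
            )
            data = simulate_kinetics(
                KineticsSpec(
                    truth=truth_s,
                    noise=0.01,
                    enzyme=enzyme,
                    substrate=substrate,
                    seed=rng_seed + sum(ord(c) for c in enzyme + substrate) % 1000,
                )
            )
            frames.append(data.table)
    write_kinetic_table(
        KineticDataset(pd.concat(frames, ignore_index=True)), out_dir / "kinetics.csv"
    )

    annotated = fig3_like_tree(seed=rng_seed)
    write_tree(annotated.phylogeny, out_dir / "tree.nwk")
    write_leaf_states(dict(annotated.leaf_states), out_dir / "states.tsv")

    ids = list(msa.ids)
    config = {
        "alignment": str(out_dir / "alignment.fasta"),
        "structure": str(out_dir / "structure.pdb"),
        "tree": str(out_dir / "tree.nwk"),
        "annotations": str(out_dir / "states.tsv"),
        "kinetics": str(out_dir / "kinetics.csv"),
        "reference_id": "REF",
        "reference_panel": ids[1:6],
        "group_a": ids[6:14],
        "group_b": ids[14:20],
        "params": {"n_perm": n_perm, "seed": seed, "min_score": 2},
    }
    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config))
    return config_path
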
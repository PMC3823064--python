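"""End-to-end orchestration from a single YAML config.

Stage order: structure shells -> column mapping/conservation -> permutation
test -> D&V selection/scoring/grouping -> Venn sets -> kinetics fits and
specificity classification -> parsimony.  Stages whose inputs are missing
from the config are skipped and marked so in the report; any stage failure
aborts with a stage-named error.  Given fixed seeds the JSON report is
reproducible bit for bit (modulo the timestamp field).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .conservation import (
    column_profiles,
    conservation_sum,
    percent_identity,
    permutation_test,
    qscores,
    venn_partition,
)
from .dv_selection import (
    DEFAULT_F_HIGH,
    DEFAULT_F_LOW,
    DEFAULT_GROUP_CUTOFF,
    DEFAULT_SHORTLIST_MIN_SCORE,
    group_candidates,
    map_columns_to_reference,
    pairwise_dv_matrix,
    pick_representatives,
    score_candidates,
    select_dv_positions,
    shortlist,
)
from .errors import ConfigurationError, SpecswapError
from .io_formats import (
    GAP,
    read_alignment,
    read_kinetic_table,
    read_leaf_states,
    read_structure,
    read_tree,
)
from .kinetics import DEFAULT_NS_BOUND_MM, fit_pingpong, specificity_ratio
from .phylo_function import AnnotatedPhylogeny, loo_accuracy, min_changes
from .structure_shells import (
    DEFAULT_D_MAX,
    DEFAULT_RADII,
    assign_shells,
    residue_min_distances,
)

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "cofactor": "PLP",
    "ligand": None,
    "radii": list(DEFAULT_RADII),
    "d_max": DEFAULT_D_MAX,
    "f_low": DEFAULT_F_LOW,
    "f_high": DEFAULT_F_HIGH,
    "cutoff": DEFAULT_GROUP_CUTOFF,
    "min_score": DEFAULT_SHORTLIST_MIN_SCORE,
    "level": 0.75,
    "n_perm": 100_000,
    "seed": 0,
    "ns_bound_mM": DEFAULT_NS_BOUND_MM,
    "qscore_scorer": "profile",
    "substitution_matrix": "BLOSUM62",
    "asp_substrate": "Asp",
    "aromatic_substrate": "Phe",
    "representative_policy": "lex",
    "distance_target": "cofactor",  # cofactor | cofactor+ligand, for D&V d_max
}


@dataclass
class PipelineConfig:
    """Input paths plus a parameter block (defaults mirror the analysis
    defaults: d_max 15 Å, variability window 0.25–0.75, group cutoff 9,
    conservation level 0.75, n_perm 100000, first shell 3.40 Å, NS bound
    40 mM)."""

    alignment: str | None = None
    structure: str | None = None
    tree: str | None = None
    annotations: str | None = None
    kinetics: str | None = None
    reference_id: str | None = None
    reference_panel: list[str] = field(default_factory=list)
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ConfigurationError(f"unknown parameter key(s): {sorted(unknown)}")
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        for key in ("alignment", "structure", "tree", "annotations", "kinetics"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"config key {key!r}: file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            "alignment": config.alignment,
            "structure": config.structure,
            "tree": config.tree,
            "annotations": config.annotations,
            "kinetics": config.kinetics,
            "reference_id": config.reference_id,
            "reference_panel": config.reference_panel,
            "group_a": config.group_a,
            "group_b": config.group_b,
            "params": config.params,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages the config provides inputs for; return the report dict."""
    p = config.params
    report: dict[str, Any] = {
        "provenance": {
            "specswap_version": __version__,
            "config_hash": _config_hash(config),
            "seed": p["seed"],
            "params": dict(p),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.monotonic()
            try:
                out = fn()
            except SpecswapError as exc:
                raise type(exc)(f"stage {name!r}: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.monotonic() - t0)
            report["stages"][name] = out if out is not None else {"status": "ok"}
            return out

        return wrap

    msa = read_alignment(config.alignment) if config.alignment else None
    structure = read_structure(config.structure) if config.structure else None
    annotations = (
        read_leaf_states(config.annotations) if config.annotations else None
    )

    distances = None
    if structure is not None:

        def _shells():
            nonlocal distances
            targets = [p["cofactor"]] + ([p["ligand"]] if p["ligand"] else [])
            shell_distances = residue_min_distances(structure, targets)
            assignment = assign_shells(shell_distances, p["radii"])
            first = assignment.residues_in_shell(1)
            distances = (
                shell_distances
                if p["distance_target"] == "cofactor+ligand"
                else residue_min_distances(structure, [p["cofactor"]])
            )
            return {
                "target": shell_distances.target_description,
                "radii": list(assignment.radii),
                "n_residues": len(shell_distances.entries),
                "first_shell_residues": first,
                "n_first_shell": len(first),
            }

        stage("shells")(_shells)
    else:
        report["stages"]["shells"] = {"status": "skipped", "reason": "no structure"}

    q = None
    column_map = None
    profiles = None
    if msa is not None:
        profiles = column_profiles(msa)
        if config.reference_id and distances is not None:
            column_map = map_columns_to_reference(msa, config.reference_id, distances)

        def _conservation():
            nonlocal q
            q = qscores(msa, matrix=p["substitution_matrix"], scorer=p["qscore_scorer"])
            out: dict[str, Any] = {"n_columns": msa.length, "n_sequences": msa.n_sequences}
            if column_map is not None:
                first_shell = report["stages"]["shells"]["first_shell_residues"]
                residue_to_col = {r: c for c, r in column_map.items()}
                observed = sorted(
                    residue_to_col[r] for r in first_shell if r in residue_to_col
                )
                ref_seq = msa.sequence(config.reference_id)
                eligible = [i for i, ch in enumerate(ref_seq, start=1) if ch != GAP]
                out["first_shell_columns"] = observed
                if observed:
                    out["qscore_sum_first_shell"] = conservation_sum(q, observed)
                    out["qscore_max_possible"] = 100.0 * len(observed)
                    perm = permutation_test(
                        q,
                        observed,
                        eligible,
                        n_perm=p["n_perm"],
                        seed=p["seed"],
                    )
                    out["permutation"] = {
                        "observed_sum": perm.observed_sum,
                        "null_max": perm.null_max,
                        "n_perm": perm.null_samples,
                        "p_value": perm.p_value,
                    }
            return out

        stage("conservation")(_conservation)
    else:
        report["stages"]["conservation"] = {"status": "skipped", "reason": "no alignment"}

    if msa is not None and column_map is not None and config.reference_panel:

        def _dv():
            positions = select_dv_positions(
                profiles, column_map, distances, p["d_max"], p["f_low"], p["f_high"]
            )
            candidates = [
                i for i in msa.ids if i not in set(config.reference_panel)
            ]
            cards = score_candidates(candidates, msa, config.reference_panel, positions)
            top = shortlist(cards, p["min_score"])
            out: dict[str, Any] = {
                "n_dv_positions": len(positions),
                "dv_columns": list(positions.columns),
                "scores": dict(sorted(cards.scores.items())),
                "shortlist": top,
            }
            if top:
                matrix = pairwise_dv_matrix(top, cards, msa)
                groups = group_candidates(matrix, p["cutoff"])
                partition = pick_representatives(
                    groups, p["representative_policy"], scorecard=cards
                )
                out["n_groups"] = len(groups)
                out["groups"] = [list(g) for g in partition.groups]
                out["representatives"] = list(partition.representatives)
            return out

        stage("dv_selection")(_dv)
    else:
        report["stages"]["dv_selection"] = {
            "status": "skipped",
            "reason": "needs alignment, structure+reference_id, and reference_panel",
        }

    if msa is not None and config.group_a and config.group_b:

        def _venn():
            venn = venn_partition(msa, config.group_a, config.group_b, p["level"])
            identities = {
                f"{a}|{b}": round(percent_identity(msa, a, b), 1)
                for i, a in enumerate(config.group_a + config.group_b)
                for b in (config.group_a + config.group_b)[i + 1 :]
            }
            return {
                "n_intersection": len(venn.set_intersection),
                "n_A_only": len(venn.set_A_only),
                "n_B_only": len(venn.set_B_only),
                "intersection": sorted(venn.set_intersection),
                "A_only": sorted(venn.set_A_only),
                "B_only": sorted(venn.set_B_only),
                "percent_identity": identities,
            }

        stage("venn")(_venn)
    else:
        report["stages"]["venn"] = {
            "status": "skipped",
            "reason": "needs alignment and both specificity groups",
        }

    if config.kinetics:

        def _kinetics():
            data = read_kinetic_table(config.kinetics)
            asp_name, aro_name = p["asp_substrate"], p["aromatic_substrate"]
            enzymes = sorted(data.table["enzyme"].unique())
            rows = []
            for enzyme in enzymes:
                subs = set(data.table.loc[data.table["enzyme"] == enzyme, "substrate"])
                if not {asp_name, aro_name} <= subs:
                    continue
                fa = fit_pingpong(data, enzyme, asp_name, ns_bound_mM=p["ns_bound_mM"])
                fb = fit_pingpong(data, enzyme, aro_name, ns_bound_mM=p["ns_bound_mM"])
                call = specificity_ratio(fa, fb)
                rows.append(
                    {
                        "enzyme": enzyme,
                        "asp_model": fa.model_used,
                        "asp_kcat": fa.params.kcat if fa.params else None,
                        "asp_Km_mM": fa.params.Km_AA if fa.params else None,
                        "asp_kcat_over_Km": fa.specificity_constant,
                        "aro_model": fb.model_used,
                        "aro_kcat": fb.params.kcat if fb.params else None,
                        "aro_Km_mM": fb.params.Km_AA if fb.params else None,
                        "aro_kcat_over_Km": fb.specificity_constant,
                        "ratio": call.rounded_ratio,
                        "label": call.label,
                    }
                )
            return {"table": rows, "n_enzymes": len(rows)}

        stage("kinetics")(_kinetics)
    else:
        report["stages"]["kinetics"] = {"status": "skipped", "reason": "no kinetic table"}

    if config.tree and annotations:

        def _parsimony():
            phylo = read_tree(config.tree)
            annotated = AnnotatedPhylogeny(phylo, annotations)
            free = min_changes(annotated)
            by_root = {s: min_changes(annotated, s).min_changes for s in ("AAT", "TAT")}
            return {
                "min_changes": free.min_changes,
                "optimal_root_states": sorted(free.optimal_root_states),
                "min_changes_by_root": by_root,
                "n_candidate_switch_edges": len(free.candidate_switch_edges),
                "loo_accuracy": loo_accuracy(annotated),
            }

        stage("parsimony")(_parsimony)
    else:
        report["stages"]["parsimony"] = {
            "status": "skipped",
            "reason": "needs tree and annotations",
        }

    return report


def write_report(report: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Write report.json plus a short human-readable report.txt; returns the
    JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = ["specswap pipeline report", "========================", ""]
    for name, stage in report["stages"].items():
        lines.append(f"[{name}]")
        if stage.get("status") == "skipped":
            lines.append(f"  skipped: {stage['reason']}")
        else:
            for key, value in stage.items():
                if isinstance(value, (int, float, str)):
                    lines.append(f"  {key}: {value}")
        lines.append("")
    (out_dir / "report.txt").write_text("\n".join(lines))
    return json_path
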
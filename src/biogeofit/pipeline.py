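"""Orchestration: score every clade in a manifest and compare tree classes.

For each clade a morphological and a molecular topology are pruned to
their shared taxa and scored against the *same* region matrix with the
same permutation budget; stratigraphic metrics are added when enough
leaves have a fossil record.  The comparison layer then runs paired
Wilcoxon signed-rank and sign tests per metric, per-subset variants
(structured matrices only, resolution-matched pairs, ...), Spearman
correlations against publication year, and Wilcoxon re-tests on OLS
residuals against year and log root age.

Every permutation stream is derived deterministically from one master
seed and the clade id, so a manifest re-run reproduces the report
exactly regardless of clade order or parallelism.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from biogeofit.biogeo import BherError, bher_test
from biogeofit.compatibility import CompatError, mcptp_test
from biogeofit.parsimony import ensemble_fit
from biogeofit.phylo import PhyloTree, parse_newick, prune_to_taxa, tree_shape_metrics
from biogeofit.regions import RegionMatrix, code_regions
from biogeofit.stratigraphy import FossilRanges, StratError, strat_metrics
from biogeofit.paired_stats import (
    PairedStatsError, ols_residuals, sign_test, spearman_corr, wilcoxon_paired,
)


@dataclass
class StudyRecord:
    """One clade's inputs: paired trees, region matrix, optional fossils."""

    clade_id: str
    morphological_tree: PhyloTree
    molecular_tree: PhyloTree
    region_matrix: Optional[RegionMatrix] = None
    occurrences: Optional[tuple] = None  # (OccurrenceTable, AreaHierarchy, RegionGeography)
    fossil_ranges: Optional[FossilRanges] = None
    metadata: dict = field(default_factory=dict)  # Year per tree, Age, Size, S/T

    def __post_init__(self):
        for key in ("year_morphological", "year_molecular", "root_age_Ma",
                    "size_morphological", "size_molecular"):
            value = self.metadata.get(key)
            if value is not None and value <= 0:
                raise ValueError(f"metadata field {key} must be positive")


def _sub_seed(master_seed: int, clade_id: str, stream: str) -> int:
    """Deterministic 31-bit substream seed from master seed + labels."""
    import zlib

    label_hash = zlib.crc32(f"{clade_id}/{stream}".encode())
    ss = np.random.SeedSequence([master_seed, label_hash])
    return int(ss.generate_state(1)[0] % (2**31))


TREE_METRICS = ["CI", "RI", "ci_ri_p", "bHER", "res", "colless",
                "SCI", "MSM_star", "GER", "GER_star"]


def run_clade(record: StudyRecord, *, n_perm: int = 10_000,
              master_seed: int = 0, min_fossil_coverage: float = 0.5) -> dict:
    """Score one clade: both trees against the shared region matrix.

    Returns a flat row dict with ``morph_*`` and ``mol_*`` columns; an
    untestable matrix flags the row (``usable = False``) and it is
    excluded from paired tests downstream.
    """
    shared = set(record.morphological_tree.leaf_labels) & set(
        record.molecular_tree.leaf_labels)
    morph = (prune_to_taxa(record.morphological_tree, shared)
             if shared != set(record.morphological_tree.leaf_labels)
             else record.morphological_tree)
    mol = (prune_to_taxa(record.molecular_tree, shared)
           if shared != set(record.molecular_tree.leaf_labels)
           else record.molecular_tree)

    if record.region_matrix is not None:
        matrix = record.region_matrix
    elif record.occurrences is not None:
        matrix = code_regions(*record.occurrences)
    else:
        raise ValueError(f"clade {record.clade_id}: no matrix or occurrences")

    if set(matrix.taxa) - shared:
        keep = [i for i, t in enumerate(matrix.taxa) if t in shared]
        matrix = RegionMatrix(
            [matrix.taxa[i] for i in keep], list(matrix.regions),
            matrix.entries[keep], dict(matrix.constituents),
            list(matrix.merge_log), matrix.untestable,
        )

    row: dict = {"clade_id": record.clade_id, "n_taxa": len(shared),
                 "n_regions": matrix.n_regions, "usable": True, **record.metadata}

    if not matrix.is_testable():
        row["usable"] = False
        row["flag"] = "untestable matrix"
        return row

    try:
        mcptp = mcptp_test(matrix, n_perm=n_perm,
                           seed=_sub_seed(master_seed, record.clade_id, "mcptp"))
        row["mcptp_p"] = mcptp.p_value
        row["n_incompatible_pairs"] = mcptp.n_incompatible_pairs
    except CompatError as exc:
        row["mcptp_p"] = math.nan
        row["flag"] = f"mcptp: {exc}"

    for prefix, tree in (("morph", morph), ("mol", mol)):
        shape = tree_shape_metrics(tree)
        row[f"{prefix}_res"] = shape.res
        row[f"{prefix}_colless"] = shape.colless
        row[f"{prefix}_n_polytomies"] = shape.n_polytomies
        row[f"{prefix}_polytomy_leaf_count"] = shape.polytomy_leaf_count
        fit = ensemble_fit(tree, matrix)
        row[f"{prefix}_CI"] = fit.ci
        row[f"{prefix}_RI"] = fit.ri
        try:
            bher = bher_test(
                tree, matrix, n_perm=n_perm,
                seed=_sub_seed(master_seed, record.clade_id, f"bher_{prefix}"))
            row[f"{prefix}_bHER"] = bher.bher
            row[f"{prefix}_ci_ri_p"] = bher.p_value
            row[f"{prefix}_L"] = bher.L_obs
            row[f"{prefix}_MEANNS"] = bher.MEANNS
        except BherError as exc:
            row["usable"] = False
            row["flag"] = f"bher {prefix}: {exc}"
        if record.fossil_ranges is not None:
            try:
                strat = strat_metrics(
                    tree, record.fossil_ranges, n_perm=n_perm,
                    seed=_sub_seed(master_seed, record.clade_id, f"strat_{prefix}"),
                    min_coverage=min_fossil_coverage)
                row[f"{prefix}_SCI"] = strat.SCI
                row[f"{prefix}_MSM_star"] = strat.MSM_star
                row[f"{prefix}_GER"] = strat.GER
                row[f"{prefix}_GER_star"] = strat.GER_star
                row[f"{prefix}_MIG"] = strat.MIG
            except StratError:
                pass  # below coverage / degenerate: stratigraphic fields stay empty
    return row


def _paired_table(df: pd.DataFrame, metrics=None) -> list[dict]:
    """Paired Wilcoxon + sign test per metric, molecular minus morphological."""
    out = []
    for metric in metrics or TREE_METRICS:
        a, b = f"mol_{metric}", f"morph_{metric}"
        if a not in df or b not in df:
            continue
        sub = df[[a, b]].dropna()
        if len(sub) < 2:
            out.append({"metric": metric, "n": len(sub), "error": "too few pairs"})
            continue
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        entry = {"metric": metric, "n": len(sub),
                 "median_molecular": float(np.median(x)),
                 "median_morphological": float(np.median(y))}
        try:
            res = wilcoxon_paired(x, y)
            entry.update(res.to_dict())
        except PairedStatsError as exc:
            entry["error"] = str(exc)
        try:
            entry["sign_test_p"] = sign_test(x, y)
            entry["wins_molecular"] = int((x > y).sum())
            entry["wins_morphological"] = int((x < y).sum())
            entry["ties"] = int((x == y).sum())
        except PairedStatsError:
            pass
        out.append(entry)
    return out


def _subset_masks(df: pd.DataFrame) -> dict[str, pd.Series]:
    masks = {"all": pd.Series(True, index=df.index)}
    if "mcptp_p" in df:
        masks["mcptp_significant"] = df["mcptp_p"] < 0.05
    if "morph_res" in df:
        masks["morph_fully_resolved"] = df["morph_res"] >= 1.0 - 1e-9
        masks["res_within_5pct"] = (df["morph_res"] - df["mol_res"]).abs() <= 0.05
        masks["both_res_ge_75pct"] = (df["morph_res"] >= 0.75) & (df["mol_res"] >= 0.75)
    if "morph_polytomy_leaf_count" in df:
        masks["equal_polytomy_leaf_count"] = (
            df["morph_polytomy_leaf_count"] == df["mol_polytomy_leaf_count"])
    return masks


def run_comparison(records_or_rows, *, n_perm: int = 10_000, master_seed: int = 0,
                   min_fossil_coverage: float = 0.5) -> dict:
    """Full study: per-clade metric rows plus the paired comparison layer.

    Accepts either :class:`StudyRecord` objects (scored here) or
    already-computed row dicts.  Returns a report dict with the per-clade
    table, paired tests (overall and per subset), win counts, Spearman
    correlations of each fit metric against publication year, and
    Wilcoxon re-tests on residuals after regressing each fit metric on
    publication year and on log root age.
    """
    rows = []
    for item in records_or_rows:
        if isinstance(item, StudyRecord):
            rows.append(run_clade(item, n_perm=n_perm, master_seed=master_seed,
                                  min_fossil_coverage=min_fossil_coverage))
        else:
            rows.append(dict(item))
    df = pd.DataFrame(rows)
    usable = df[df.get("usable", pd.Series(True, index=df.index)).fillna(False)]
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable clades")

    report: dict = {
        "n_clades": len(df),
        "n_usable": len(usable),
        "n_flagged": int(len(df) - len(usable)),
        "per_clade": rows,
        "paired_tests": {},
        "correlations_vs_year": {},
        "residual_tests": {},
        "seed": master_seed,
        "n_perm": n_perm,
    }

    for name, mask in _subset_masks(usable).items():
        sub = usable[mask.fillna(False)]
        if len(sub) < 2:
            report["paired_tests"][name] = {"error": "too few clades", "n": len(sub)}
            continue
        report["paired_tests"][name] = _paired_table(sub)

    # research-time analysis: metric vs publication year over all trees
    for metric in ("CI", "RI", "bHER", "ci_ri_p"):
        values, years = [], []
        for prefix, year_col in (("morph", "year_morphological"),
                                 ("mol", "year_molecular")):
            col = f"{prefix}_{metric}"
            if col in usable and year_col in usable:
                sub = usable[[col, year_col]].dropna()
                values.extend(sub[col].tolist())
                years.extend(sub[year_col].tolist())
        if len(values) >= 3 and len(set(years)) > 1:
            rs, p = spearman_corr(years, values)
            report["correlations_vs_year"][metric] = {"rs": rs, "p": p, "n": len(values)}

    # residual re-tests: regress metric on a covariate over all 2n trees,
    # then compare paired residuals
    for covariate, transform in (("year", None), ("log_age", "log")):
        for metric in ("CI", "RI", "bHER"):
            result = _residual_retest(usable, metric, covariate, transform)
            if result is not None:
                report["residual_tests"][f"{metric}_vs_{covariate}"] = result
    return report


def _residual_retest(df: pd.DataFrame, metric: str, covariate: str,
                     transform: Optional[str]) -> Optional[dict]:
    if covariate == "year":
        cov_cols = ("year_morphological", "year_molecular")
    else:
        cov_cols = ("root_age_Ma", "root_age_Ma")
    a, b = f"morph_{metric}", f"mol_{metric}"
    needed = [a, b, *dict.fromkeys(cov_cols)]
    if any(c not in df for c in needed):
        return None
    sub = df[needed].dropna()
    if len(sub) < 3:
        return None
    y = np.concatenate([sub[a].to_numpy(), sub[b].to_numpy()])
    x = np.concatenate([sub[cov_cols[0]].to_numpy(), sub[cov_cols[1]].to_numpy()])
    if transform == "log":
        if (x <= 0).any():
            return None
        x = np.log(x)
    if len(set(x)) < 2:
        return None
    resid = ols_residuals(y, x)
    n = len(sub)
    try:
        res = wilcoxon_paired(resid[n:], resid[:n])  # molecular minus morphological
    except PairedStatsError as exc:
        return {"error": str(exc), "n": n}
    return {**res.to_dict(), "n": n}


# ---------------------------------------------------------------------------
# manifest I/O


def load_manifest(path) -> list[StudyRecord]:
    """CSV manifest: clade_id, morph_tree, mol_tree, matrix[, ranges, stages]
    plus optional metadata columns (year_morphological, year_molecular,
    root_age_Ma, size_morphological, size_molecular).  Paths are relative
    to the manifest's directory."""
    from biogeofit.stratigraphy import StageTable, assign_fad_ages, read_ranges_csv

    base = Path(path).parent
    records = []
    with open(path, newline="") as fh:
        for rowdict in csv.DictReader(fh):
            morph = parse_newick((base / rowdict["morph_tree"]).read_text())
            mol = parse_newick((base / rowdict["mol_tree"]).read_text())
            mpath = base / rowdict["matrix"]
            matrix = (RegionMatrix.from_nexus(mpath) if mpath.suffix == ".nex"
                      else RegionMatrix.from_csv(mpath))
            fossils = None
            if rowdict.get("ranges") and rowdict.get("stages"):
                stages = StageTable.from_csv(base / rowdict["stages"])
                fossils = assign_fad_ages(
                    read_ranges_csv(base / rowdict["ranges"]), stages)
            metadata = {
                k: float(v) for k, v in rowdict.items()
                if k in ("year_morphological", "year_molecular", "root_age_Ma",
                         "size_morphological", "size_molecular") and v
            }
            records.append(StudyRecord(
                clade_id=rowdict["clade_id"], morphological_tree=morph,
                molecular_tree=mol, region_matrix=matrix,
                fossil_ranges=fossils, metadata=metadata))
    return records


def write_report(report: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report["per_clade"]).to_csv(out / "per_clade.csv", index=False)
    paired = report["paired_tests"].get("all")
    if isinstance(paired, list):
        pd.DataFrame(paired).to_csv(out / "paired_tests.csv", index=False)
    slim = {k: v for k, v in report.items() if k != "per_clade"}
    (out / "summary.json").write_text(json.dumps(slim, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
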
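"""Benchmarking procedures for grouping methods.

Covers probe-mining binder detection (select a known binder, occlude all other
labels, mark everything co-clustered with the probe as a predicted binder),
threshold sweeps with best-F1 selection and precision-recall curves,
pair-based co-clustering Jaccard between two partitions, combined-method
binder recovery, the multiple-occupancy consistent cluster members (MOCM)
fraction for epitope binning, and the pairwise-identity diversity diagnostic.

Probe evaluation is strictly label-occluding by construction: clustering runs
never receive labels; labels enter only here, after the partition is fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import Clustering, MethodConfig, cluster_repertoire
from .repertoire import (
    AntibodyRecord,
    ConfigurationError,
    ValidationError,
    extract_region,
)
from .similarity import levenshtein_identity

logger = logging.getLogger("abclust")


# ---------------------------------------------------------------------------
# Probe-mining binder detection
# ---------------------------------------------------------------------------

@dataclass
class ProbeEvalResult:
    """Confusion-matrix metrics of one probe-mining evaluation."""

    probe_ids: list[str]
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    flags: list[str] = field(default_factory=list)

    @property
    def predicted_positives(self) -> int:
        return self.tp + self.fp


def _f1(precision: float, recall: float) -> float:
    return (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )


def predicted_binders(
    clustering: Clustering, probe_ids: Sequence[str]
) -> set[str]:
    """Non-probe records sharing a cluster with any probe."""
    probe_set = set(probe_ids)
    probe_clusters = {clustering.assignment[p] for p in probe_set}
    return {
        rid
        for rid, cid in clustering.assignment.items()
        if cid in probe_clusters and rid not in probe_set
    }


def probe_binder_eval(
    clustering: Clustering,
    probe_ids: Sequence[str],
    labels: Mapping[str, bool],
) -> ProbeEvalResult:
    """Score a clustering by probe mining with occluded labels.

    Every probe must be a labeled binder present in the clustering. Predicted
    positives are the non-probe records co-clustered with any probe; metrics
    are computed against the (occluded) labels over all non-probe records.
    Precision with zero predicted positives is defined as 0 (flagged).
    """
    for probe in probe_ids:
        if probe not in clustering.assignment:
            raise ValidationError(f"probe {probe!r} absent from clustering")
        if not labels.get(probe, False):
            raise ConfigurationError(f"probe {probe!r} is not a labeled binder")
    probe_set = set(probe_ids)
    evaluated = [rid for rid in clustering.assignment if rid not in probe_set]
    missing = [rid for rid in evaluated if rid not in labels]
    if missing:
        raise ValidationError(f"records without binder labels: {missing[:10]}")
    positives = predicted_binders(clustering, probe_ids)
    tp = sum(1 for rid in positives if labels[rid])
    fp = len(positives) - tp
    fn = sum(1 for rid in evaluated if labels[rid]) - tp
    tn = len(evaluated) - tp - fp - fn
    flags = []
    if not positives:
        flags.append("zero_predicted_positives")
        precision = 0.0
    else:
        precision = tp / len(positives)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return ProbeEvalResult(
        probe_ids=list(probe_ids),
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        flags=flags,
    )


def averaged_probe_eval(
    clustering: Clustering,
    labels: Mapping[str, bool],
    probes: Sequence[str] | None = None,
) -> tuple[ProbeEvalResult, pd.DataFrame]:
    """Probe mining with every labeled binder (or a fixed set) as sole probe.

    Returns the arithmetic mean of per-probe precision/recall/F1 (counts are
    summed for reference) plus the full per-probe table. Fixed probe sets are
    evaluated jointly in a single run (train-antibodies-as-probes mode).
    """
    if probes is not None:
        result = probe_binder_eval(clustering, probes, labels)
        per_probe = pd.DataFrame([vars(result)])
        return result, per_probe
    binders = sorted(
        rid for rid in clustering.assignment if labels.get(rid, False)
    )
    if not binders:
        raise ConfigurationError("no labeled binders to use as probes")
    results = [probe_binder_eval(clustering, [b], labels) for b in binders]
    per_probe = pd.DataFrame(
        {
            "probe": binders,
            "precision": [r.precision for r in results],
            "recall": [r.recall for r in results],
            "f1": [r.f1 for r in results],
            "tp": [r.tp for r in results],
            "fp": [r.fp for r in results],
            "fn": [r.fn for r in results],
            "tn": [r.tn for r in results],
        }
    )
    mean = ProbeEvalResult(
        probe_ids=binders,
        precision=float(per_probe["precision"].mean()),
        recall=float(per_probe["recall"].mean()),
        f1=float(per_probe["f1"].mean()),
        tp=int(per_probe["tp"].sum()),
        fp=int(per_probe["fp"].sum()),
        fn=int(per_probe["fn"].sum()),
        tn=int(per_probe["tn"].sum()),
        flags=sorted({f for r in results for f in r.flags}),
    )
    return mean, per_probe


# ---------------------------------------------------------------------------
# Threshold sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepTable:
    """Full sweep table plus per-method best rows and PR-curve points."""

    table: pd.DataFrame
    per_probe: dict[int, pd.DataFrame] = field(default_factory=dict)

    def best(self) -> pd.DataFrame:
        ok = self.table[self.table["status"] == "ok"]
        idx = ok.groupby("method")["f1"].idxmax()
        return ok.loc[idx].reset_index(drop=True)

    def pr_points(self) -> pd.DataFrame:
        ok = self.table[self.table["status"] == "ok"]
        return ok.sort_values(["method", "threshold"])[
            ["method", "threshold", "precision", "recall", "predicted_positives"]
        ].reset_index(drop=True)


def sweep(
    records: Sequence[AntibodyRecord],
    grid: Sequence[MethodConfig],
    labels: Mapping[str, bool],
    structures=None,
    embeddings=None,
    paratopes=None,
    probes: Sequence[str] | None = None,
) -> SweepTable:
    """Evaluate every config in the grid by (averaged) probe mining.

    Invalid configs are marked failed and the sweep continues. The table
    mirrors the published best-parametrization layout: method, threshold,
    cl_res (selector), cl_len (stratification), method_specific, plus
    precision/recall/F1 and mean predicted-positive counts.
    """
    if not grid:
        raise ConfigurationError("empty sweep grid")
    rows = []
    per_probe: dict[int, pd.DataFrame] = {}
    for i, config in enumerate(grid):
        row = {
            "config_index": i,
            "method": config.method,
            "threshold": config.threshold,
            "cl_res": config.selector,
            "cl_len": str(config.stratification),
            "method_specific": repr(config.method_specific) or "none",
            "algorithm": config.algorithm,
        }
        try:
            clustering = cluster_repertoire(
                records,
                config,
                structures=structures,
                embeddings=embeddings,
                paratopes=paratopes,
            )
            result, table = averaged_probe_eval(clustering, labels, probes=probes)
            n_probes = len(table)
            row.update(
                precision=result.precision,
                recall=result.recall,
                f1=result.f1,
                predicted_positives=(result.tp + result.fp) / max(n_probes, 1),
                n_clusters=clustering.n_clusters,
                status="ok",
            )
            per_probe[i] = table
        except (ValidationError, ConfigurationError, ValueError) as exc:
            logger.warning("sweep config %d failed: %s", i, exc)
            row.update(
                precision=np.nan,
                recall=np.nan,
                f1=np.nan,
                predicted_positives=np.nan,
                n_clusters=0,
                status=f"failed: {exc}",
            )
        rows.append(row)
    return SweepTable(table=pd.DataFrame(rows), per_probe=per_probe)


# ---------------------------------------------------------------------------
# Partition comparison
# ---------------------------------------------------------------------------

def jaccard_coclustering(c1: Clustering, c2: Clustering) -> float:
    """Pair-based Jaccard index between two partitions of the same ids.

    Over all unordered record pairs, S1/S2 are the co-clustered pair sets;
    returns |S1 n S2| / |S1 u S2|. 1.0 iff the partitions are identical up to
    relabeling; both all-singleton -> 1.0 with a warning.
    """
    if set(c1.assignment) != set(c2.assignment):
        raise ValidationError("clusterings cover different record-id sets")
    s1 = sum(comb(n, 2) for n in _cluster_sizes(c1).values())
    s2 = sum(comb(n, 2) for n in _cluster_sizes(c2).values())
    joint: dict[tuple[str, str], int] = {}
    for rid, cid in c1.assignment.items():
        key = (cid, c2.assignment[rid])
        joint[key] = joint.get(key, 0) + 1
    inter = sum(comb(n, 2) for n in joint.values())
    union = s1 + s2 - inter
    if union == 0:
        logger.warning("both clusterings are all-singleton; Jaccard defined as 1.0")
        return 1.0
    return inter / union


def _cluster_sizes(clustering: Clustering) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for cid in clustering.assignment.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    return sizes


def combined_binder_fraction(
    c1: Clustering,
    c2: Clustering,
    probes: Sequence[str],
    labels: Mapping[str, bool],
) -> dict[str, float]:
    """Fraction of binders recovered by each method and by their union.

    The denominator is the number of labeled binders excluding probes; the
    union fraction is computed on the union of the two predicted-positive
    sets, so it is always >= each individual fraction.
    """
    for clustering in (c1, c2):
        probe_binder_eval(clustering, probes, labels)  # validates inputs
    probe_set = set(probes)
    binders = {
        rid
        for rid in c1.assignment
        if rid not in probe_set and labels.get(rid, False)
    }
    if not binders:
        raise ConfigurationError("no non-probe labeled binders")
    found1 = predicted_binders(c1, probes) & binders
    found2 = predicted_binders(c2, probes) & binders
    return {
        "method_a": len(found1) / len(binders),
        "method_b": len(found2) / len(binders),
        "union": len(found1 | found2) / len(binders),
    }


# ---------------------------------------------------------------------------
# Epitope binning (MOCM)
# ---------------------------------------------------------------------------

def mocm_fraction(
    clustering: Clustering,
    epitope_labels: Mapping[str, str],
    include_singletons: bool = True,
) -> float:
    """Multiple-occupancy consistent cluster members fraction.

    Numerator: total members of size->=2 clusters whose members all share one
    epitope label. Denominator: all clustered records (singletons included,
    the default) or, with ``include_singletons=False``, only members of
    multi-occupancy clusters.
    """
    unlabeled = [rid for rid in clustering.assignment if rid not in epitope_labels]
    if unlabeled:
        raise ValidationError(
            f"records without epitope labels: {sorted(unlabeled)[:10]}"
        )
    consistent = 0
    multi_members = 0
    for members in clustering.clusters().values():
        if len(members) < 2:
            continue
        multi_members += len(members)
        if len({epitope_labels[rid] for rid in members}) == 1:
            consistent += len(members)
    denom = len(clustering.assignment) if include_singletons else multi_members
    return consistent / denom if denom else 0.0


def normalized_threshold_curve(
    records: Sequence[AntibodyRecord],
    config: MethodConfig,
    thresholds: Sequence[float],
    epitope_labels: Mapping[str, str],
    structures=None,
    embeddings=None,
    paratopes=None,
    include_singletons: bool = True,
) -> list[tuple[float, float]]:
    """MOCM along a threshold range, mapped linearly onto [0, 1].

    Range endpoints map to 0 and 1 exactly; a single-point range maps to a
    single point at 0. Normalization makes curves from methods with
    incommensurable threshold units overlayable.
    """
    from dataclasses import replace

    thresholds = list(thresholds)
    if not thresholds:
        raise ConfigurationError("empty threshold range")
    lo, hi = min(thresholds), max(thresholds)
    span = hi - lo
    points = []
    for t in thresholds:
        clustering = cluster_repertoire(
            records,
            replace(config, threshold=t),
            structures=structures,
            embeddings=embeddings,
            paratopes=paratopes,
        )
        mocm = mocm_fraction(clustering, epitope_labels, include_singletons)
        norm = (t - lo) / span if span > 0 else 0.0
        points.append((norm, mocm))
    return points


def binning_comparison(
    records: Sequence[AntibodyRecord],
    families: Mapping[str, tuple[MethodConfig, Sequence[float]]],
    epitope_labels: Mapping[str, str],
    structures=None,
    embeddings=None,
    paratopes=None,
) -> pd.DataFrame:
    """Overlay normalized-threshold MOCM curves for several method families."""
    rows = []
    for name, (config, thresholds) in families.items():
        curve = normalized_threshold_curve(
            records,
            config,
            thresholds,
            epitope_labels,
            structures=structures,
            embeddings=embeddings,
            paratopes=paratopes,
        )
        for (norm, mocm), t in zip(curve, thresholds):
            rows.append(
                {
                    "method": name,
                    "threshold": t,
                    "normalized_threshold": norm,
                    "mocm": mocm,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diversity diagnostic
# ---------------------------------------------------------------------------

def identity_distribution(
    records: Sequence[AntibodyRecord],
    selector: str,
    max_exact_n: int = 2000,
    max_sampled_pairs: int = 500_000,
    seed: int = 0,
) -> dict:
    """Pairwise Levenshtein-identity summary over a region.

    All-vs-all for up to ``max_exact_n`` records; above that, a seeded random
    subsample of pairs. Returns mean, deciles (0th..100th percentile) and a
    20-bin histogram of identities.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 records")
    seqs = [extract_region(rec, selector) for rec in records]
    n = len(seqs)
    identities: list[float] = []
    if n <= max_exact_n:
        for i in range(n):
            for j in range(i + 1, n):
                identities.append(levenshtein_identity(seqs[i], seqs[j]))
    else:
        rng = np.random.default_rng(seed)
        for _ in range(max_sampled_pairs):
            i, j = rng.choice(n, size=2, replace=False)
            identities.append(levenshtein_identity(seqs[i], seqs[j]))
    arr = np.asarray(identities)
    counts, edges = np.histogram(arr, bins=20, range=(0.0, 1.0))
    return {
        "n_records": n,
        "n_pairs": len(identities),
        "mean": float(arr.mean()),
        "deciles": [float(v) for v in np.percentile(arr, np.arange(0, 101, 10))],
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
        "exact": n <= max_exact_n,
    }
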
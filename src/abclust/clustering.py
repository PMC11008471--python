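"""Stratify-then-cluster engine shared by all five grouping methods.

Records are first split into strata (gene calls and/or region lengths); within
each stratum a pairwise distance is clustered either by a single-pass greedy
leader algorithm (the default, after the SPACE scheme: an item joins the first
representative within threshold or founds a new cluster) or by agglomerative
linkage cut at the threshold. Threshold comparisons are inclusive
(d <= threshold joins), so an identity threshold of 1.0 keeps only exact
matches together and a distance threshold of 0 yields singletons on distinct
items.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .repertoire import (
    AntibodyRecord,
    ConfigurationError,
    Stratification,
    ValidationError,
    check_unique_ids,
    resolve_selector,
    strat_key,
)
from . import similarity as sim

METHODS = ("clonotype", "sequence", "paratope", "structure", "embedding")

#: method aliases seen in published tables
METHOD_ALIASES = {"seq": "sequence", "structural": "structure", "space2": "structure"}


@dataclass
class MethodConfig:
    """One parametrization cell of the grouping-method grid.

    ``threshold`` is always in the method's *distance* units; construct from a
    published identity threshold t with ``identity_threshold=t`` (stored as
    1 - t). ``method_specific`` carries per-method options: ``genes`` (v|vj)
    for clonotype, ``superpose_on`` for structure, ``metric`` for embedding,
    ``binarization`` for paratope.
    """

    method: str
    threshold: float
    selector: str = "cdrh3"
    stratification: Stratification = field(default_factory=Stratification)
    method_specific: dict = field(default_factory=dict)
    algorithm: str = "greedy"
    linkage_type: str = "complete"
    assign: str = "first"  # greedy: first qualifying vs nearest qualifying rep

    def __post_init__(self) -> None:
        self.method = METHOD_ALIASES.get(self.method, self.method)
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        if self.algorithm not in ("greedy", "linkage"):
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if self.linkage_type not in ("single", "complete", "average"):
            raise ConfigurationError(f"unknown linkage {self.linkage_type!r}")
        if isinstance(self.stratification, str):
            self.stratification = Stratification.parse(self.stratification)
        if self.method == "structure" and self.stratification.length_of is None:
            raise ConfigurationError(
                "structure clustering requires a length stratification scheme"
            )
        if self.method == "clonotype":
            self.method_specific.setdefault("genes", "v")

    @classmethod
    def from_dict(cls, data: Mapping) -> "MethodConfig":
        data = dict(data)
        if "identity_threshold" in data:
            data["threshold"] = 1.0 - float(data.pop("identity_threshold"))
        if "stratification" in data and isinstance(data["stratification"], str):
            data["stratification"] = Stratification.parse(data["stratification"])
        known = {
            "method",
            "threshold",
            "selector",
            "stratification",
            "method_specific",
            "algorithm",
            "linkage_type",
            "assign",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "list[MethodConfig]":
        """Load one config or a list of configs from a YAML file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, Mapping):
            data = [data]
        return [cls.from_dict(item) for item in data]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "threshold": self.threshold,
            "selector": self.selector,
            "stratification": str(self.stratification),
            "method_specific": dict(self.method_specific),
            "algorithm": self.algorithm,
            "linkage_type": self.linkage_type,
            "assign": self.assign,
        }


@dataclass
class Clustering:
    """A partition of record ids into clusters, with stratum provenance.

    Cluster ids are globally unique and stable: ``<stratum key>|<counter>``.
    Every cluster's representative is a member of that cluster, and no two
    records from different strata ever share a cluster.
    """

    assignment: dict[str, str]
    representatives: dict[str, str]
    config: MethodConfig | None = None
    strata: dict[str, tuple] = field(default_factory=dict)

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid, cid in self.assignment.items():
            out.setdefault(cid, []).append(rid)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, ids: Sequence[str]) -> list[str]:
        return [self.assignment[i] for i in ids]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": rid,
                "cluster_id": cid,
                "stratum": str(self.strata.get(rid, ())),
                "is_representative": self.representatives.get(cid) == rid,
            }
            for rid, cid in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Clustering":
        df = pd.read_csv(path, sep="\t", dtype={"record_id": str, "cluster_id": str})
        assignment = dict(zip(df["record_id"], df["cluster_id"]))
        reps: dict[str, str] = {}
        if "is_representative" in df.columns:
            for _, row in df[df["is_representative"].astype(bool)].iterrows():
                reps[row["cluster_id"]] = row["record_id"]
        return cls(assignment=assignment, representatives=reps)


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

def greedy_leader_cluster(
    ids: Sequence[str],
    dist: Callable[[str, str], float],
    threshold: float,
    assign: str = "first",
) -> Clustering:
    """Single-pass greedy leader clustering (SPACE-style).

    Ids are processed in the given order; an id joins the first existing
    cluster whose representative is within the (inclusive) threshold, else it
    founds a new cluster and becomes its representative. ``assign="nearest"``
    instead joins the nearest qualifying representative. Deterministic given
    the input order; every member ends within threshold of its representative.
    """
    reps: list[tuple[str, str]] = []  # (cluster_id, representative id)
    assignment: dict[str, str] = {}
    representatives: dict[str, str] = {}
    for rid in ids:
        chosen = None
        best = np.inf
        for cid, rep in reps:
            try:
                d = dist(rid, rep)
            except Exception as exc:  # noqa: BLE001 - re-raise with pair context
                raise RuntimeError(
                    f"distance failed on pair ({rid!r}, {rep!r}): {exc}"
                ) from exc
            if d <= threshold:
                if assign == "first":
                    chosen = cid
                    break
                if d < best:
                    best, chosen = d, cid
        if chosen is None:
            cid = f"c{len(reps)}"
            reps.append((cid, rid))
            representatives[cid] = rid
            assignment[rid] = cid
        else:
            assignment[rid] = chosen
    return Clustering(assignment=assignment, representatives=representatives)


def linkage_cluster(
    ids: Sequence[str],
    dist: Callable[[str, str], float],
    threshold: float,
    linkage_type: str = "complete",
) -> Clustering:
    """Agglomerative clustering cut at the threshold (exhaustive all-vs-all).

    Representative = member minimizing summed distance to co-members
    (medoid), ties broken by lexicographically smallest id.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    ids = list(ids)
    n = len(ids)
    if n == 1:
        return Clustering(
            assignment={ids[0]: "c0"}, representatives={"c0": ids[0]}
        )
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = dist(ids[i], ids[j])
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"distance failed on pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = d
    z = linkage(squareform(mat, checks=False), method=linkage_type)
    flat = fcluster(z, t=threshold, criterion="distance")
    assignment: dict[str, str] = {}
    representatives: dict[str, str] = {}
    # relabel clusters deterministically by first appearance in input order
    relabel: dict[int, str] = {}
    for idx, lab in enumerate(flat):
        if lab not in relabel:
            relabel[lab] = f"c{len(relabel)}"
        assignment[ids[idx]] = relabel[lab]
    for lab, cid in relabel.items():
        member_idx = [i for i, l in enumerate(flat) if l == lab]
        sums = mat[np.ix_(member_idx, member_idx)].sum(axis=1)
        best = min(
            range(len(member_idx)),
            key=lambda k: (sums[k], ids[member_idx[k]]),
        )
        representatives[cid] = ids[member_idx[best]]
    return Clustering(assignment=assignment, representatives=representatives)


# ---------------------------------------------------------------------------
# Repertoire-level clustering
# ---------------------------------------------------------------------------

def _effective_stratification(config: MethodConfig) -> Stratification:
    strat = config.stratification
    if config.method == "clonotype":
        genes = config.method_specific.get("genes", "v")
        strat = Stratification(
            genes=genes, length_of=strat.length_of, strip_alleles=strat.strip_alleles
        )
    return strat


def _distance_function(
    config: MethodConfig,
    by_id: Mapping[str, AntibodyRecord],
    structures: Mapping[str, sim.StructureModel] | None,
    embeddings: Mapping[str, sim.EmbeddingRecord] | None,
    paratopes: Mapping[str, sim.ParatopeProfile] | None,
) -> Callable[[str, str], float]:
    method = config.method
    if method in ("sequence", "clonotype"):
        selector = config.selector

        def dist(a: str, b: str) -> float:
            return sim.region_distance(by_id[a], by_id[b], selector)

    elif method == "paratope":
        assert paratopes is not None
        binarization = config.method_specific.get("binarization")
        if binarization is not None:
            for prof in paratopes.values():
                prof.binarization_threshold = float(binarization)
        length_stratified = config.stratification.length_of is not None

        def dist(a: str, b: str) -> float:
            return sim.paratope_distance(
                by_id[a], by_id[b], paratopes[a], paratopes[b], length_stratified
            )

    elif method == "structure":
        assert structures is not None
        selector = config.selector
        superpose_on = config.method_specific.get("superpose_on")

        def dist(a: str, b: str) -> float:
            return sim.structure_distance(
                by_id[a], by_id[b], structures[a], structures[b], selector, superpose_on
            )

    elif method == "embedding":
        assert embeddings is not None
        selector = config.selector
        metric = config.method_specific.get("metric", "cosine")

        def dist(a: str, b: str) -> float:
            return sim.embedding_distance(
                embeddings[a], embeddings[b], by_id[a], by_id[b], selector, metric
            )

    else:  # pragma: no cover - guarded by MethodConfig
        raise ConfigurationError(f"unknown method {method!r}")
    return dist


def _check_aux(
    config: MethodConfig,
    records: Sequence[AntibodyRecord],
    structures,
    embeddings,
    paratopes,
) -> None:
    need = {"structure": structures, "embedding": embeddings, "paratope": paratopes}
    aux = need.get(config.method)
    if config.method in need:
        if aux is None:
            raise ValidationError(
                f"{config.method} clustering requires auxiliary data"
            )
        missing = [r.record_id for r in records if r.record_id not in aux]
        if missing:
            raise ValidationError(
                f"{config.method} data missing for records: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )


def _selection_length_key(record: AntibodyRecord, selector: str) -> tuple:
    parts = resolve_selector(selector)
    key = []
    for part in parts:
        if part in ("heavy", "light"):
            key.append(len(record.chain_seq(part)))
        else:
            start, end = record.region_bounds[part]
            key.append(end - start)
    return tuple(key)


def cluster_repertoire(
    records: Sequence[AntibodyRecord],
    config: MethodConfig,
    structures: Mapping[str, sim.StructureModel] | None = None,
    embeddings: Mapping[str, sim.EmbeddingRecord] | None = None,
    paratopes: Mapping[str, sim.ParatopeProfile] | None = None,
    shuffle_seed: int | None = None,
) -> Clustering:
    """Cluster a repertoire under one method parametrization.

    Records are split by the effective stratification (gene scheme folded in
    for clonotype; the structure method additionally extends each stratum by
    the tuple of selected-region lengths so RMSDs are only computed on
    length-matched selections), then each stratum is clustered with the
    configured engine. Strata of size 1 become singleton clusters with no
    distance computed. ``shuffle_seed`` optionally shuffles the greedy
    processing order (seeded), otherwise input order is used.
    """
    check_unique_ids(records)
    _check_aux(config, records, structures, embeddings, paratopes)
    by_id = {r.record_id: r for r in records}
    strat = _effective_stratification(config)

    strata: dict[tuple, list[str]] = {}
    strata_of: dict[str, tuple] = {}
    for rec in records:
        key = strat_key(rec, strat)
        if config.method == "structure":
            key = key + _selection_length_key(rec, config.selector)
        strata.setdefault(key, []).append(rec.record_id)
        strata_of[rec.record_id] = key

    dist = _distance_function(config, by_id, structures, embeddings, paratopes)

    assignment: dict[str, str] = {}
    representatives: dict[str, str] = {}
    for key in sorted(strata, key=repr):
        members = strata[key]
        prefix = ",".join(map(str, key)) if key else "all"
        if len(members) == 1:
            cid = f"{prefix}|0"
            assignment[members[0]] = cid
            representatives[cid] = members[0]
            continue
        order = list(members)
        if shuffle_seed is not None and config.algorithm == "greedy":
            random.Random(shuffle_seed).shuffle(order)
        if config.algorithm == "greedy":
            sub = greedy_leader_cluster(order, dist, config.threshold, config.assign)
        else:
            sub = linkage_cluster(order, dist, config.threshold, config.linkage_type)
        for rid, cid in sub.assignment.items():
            assignment[rid] = f"{prefix}|{cid[1:]}"
        for cid, rep in sub.representatives.items():
            representatives[f"{prefix}|{cid[1:]}"] = rep
    return Clustering(
        assignment=assignment,
        representatives=representatives,
        config=config,
        strata=strata_of,
    )
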
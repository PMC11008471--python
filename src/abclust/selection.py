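"""Two-step diversity selection.

Cluster the full set with one method, take each cluster's representative,
then re-cluster the representatives with a second method along a different
diversity dimension (e.g. structural step 1, embedding step 2). The final
picks are the step-2 representatives: a candidate list with redundancy
reduced along both dimensions, with full provenance so every input record
traces to exactly one final pick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .clustering import Clustering, MethodConfig, cluster_repertoire
from .repertoire import AntibodyRecord

logger = logging.getLogger("abclust")


@dataclass
class SelectionReport:
    """Outcome of a two-step selection, with provenance.

    ``provenance`` maps each final pick to its (step1 cluster, step2 cluster);
    ``pick_for`` routes any input record to its final pick via its step-1
    representative's step-2 cluster.
    """

    step1: Clustering
    step1_representatives: list[str]
    step2: Clustering
    final_picks: list[str]
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)

    def pick_for(self, record_id: str) -> str:
        rep = self.step1.representatives[self.step1.assignment[record_id]]
        step2_cluster = self.step2.assignment[rep]
        return self.step2.representatives[step2_cluster]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid in sorted(self.step1.assignment):
            c1 = self.step1.assignment[rid]
            rep1 = self.step1.representatives[c1]
            rows.append(
                {
                    "record_id": rid,
                    "step1_cluster": c1,
                    "step1_representative": rep1,
                    "step2_cluster": self.step2.assignment[rep1],
                    "final_pick": self.pick_for(rid),
                    "is_final_pick": rid in set(self.final_picks),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def two_step_select(
    records: Sequence[AntibodyRecord],
    config_a: MethodConfig,
    config_b: MethodConfig,
    structures=None,
    embeddings=None,
    paratopes=None,
) -> SelectionReport:
    """Select a diversity-enriched candidate list with two grouping methods.

    Step 1 clusters all records with ``config_a``; its representatives are
    re-clustered with ``config_b`` (representatives only); final picks are the
    step-2 representatives. Representative choice inherits from the clustering
    engine (greedy: the cluster founder; linkage: the medoid). Identical
    configs are allowed but warned as degenerate.
    """
    if config_a.to_dict() == config_b.to_dict():
        logger.warning("two_step_select: step-1 and step-2 configs are identical")
    step1 = cluster_repertoire(
        records,
        config_a,
        structures=structures,
        embeddings=embeddings,
        paratopes=paratopes,
    )
    rep_ids = sorted(set(step1.representatives.values()))
    by_id: Mapping[str, AntibodyRecord] = {r.record_id: r for r in records}
    rep_records = [by_id[rid] for rid in rep_ids]
    step2 = cluster_repertoire(
        rep_records,
        config_b,
        structures=structures,
        embeddings=embeddings,
        paratopes=paratopes,
    )
    final_picks = sorted(set(step2.representatives.values()))
    provenance = {
        pick: (step1.assignment[pick], step2.assignment[pick])
        for pick in final_picks
    }
    return SelectionReport(
        step1=step1,
        step1_representatives=rep_ids,
        step2=step2,
        final_picks=final_picks,
        provenance=provenance,
    )
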
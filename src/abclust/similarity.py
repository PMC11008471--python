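"""Pairwise similarity measures on a common distance contract.

Every measure is exposed as a *distance*: smaller means more similar, zero on
identical inputs, symmetric. Sequence-flavored measures (sequence, clonotype,
paratope) live on [0, 1] as 1 - identity; the embedding measure is cosine
distance on [0, 2]; the structure measure is an RMSD in Angstroms on [0, inf).
An identity threshold t from the literature therefore maps to a distance
threshold 1 - t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

from .repertoire import (
    AntibodyRecord,
    AnnotationError,
    ValidationError,
    extract_region,
    resolve_selector,
)

logger = logging.getLogger("abclust")

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_warned_alphabet = False


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def levenshtein_identity(a: str, b: str) -> float:
    """Normalized Levenshtein identity: 1 - L(a,b)/max(|a|,|b|).

    Both strings empty -> 1.0; exactly one empty -> 0.0. Alphabet-agnostic:
    non-amino-acid characters are accepted (logged once per process).
    """
    global _warned_alphabet
    if not _warned_alphabet and (set(a) - _AA or set(b) - _AA):
        logger.warning("non-amino-acid characters seen in identity calculation")
        _warned_alphabet = True
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def region_distance(
    rec_a: AntibodyRecord, rec_b: AntibodyRecord, selector: str
) -> float:
    """1 - Levenshtein identity of the selected regions of two records."""
    return 1.0 - levenshtein_identity(
        extract_region(rec_a, selector), extract_region(rec_b, selector)
    )


# ---------------------------------------------------------------------------
# Paratope
# ---------------------------------------------------------------------------

@dataclass
class ParatopeProfile:
    """Per-residue paratope probabilities for one record.

    ``probabilities`` maps ``(chain, 0-based index)`` to a probability in
    [0, 1]; the profile is binarized at ``binarization_threshold`` before any
    identity is computed (predicted probabilities are an input here; the
    predictor itself is upstream).
    """

    record_id: str
    probabilities: dict[tuple[str, int], float] = field(default_factory=dict)
    binarization_threshold: float = 0.5

    def validate_against(self, record: AntibodyRecord) -> None:
        if self.record_id != record.record_id:
            raise ValidationError(
                f"profile {self.record_id} does not match record {record.record_id}"
            )
        for (chain, idx), p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"{self.record_id}: probability {p} at ({chain},{idx}) "
                    "outside [0,1]"
                )
            if idx < 0 or idx >= len(record.chain_seq(chain)):
                raise ValidationError(
                    f"{self.record_id}: paratope position ({chain},{idx}) "
                    "outside chain"
                )

    def flagged(self) -> set[tuple[str, int]]:
        t = self.binarization_threshold
        return {pos for pos, p in self.probabilities.items() if p >= t}


def _paratope_coordinate(
    record: AntibodyRecord, chain: str, idx: int, by_index: bool
) -> tuple:
    """Comparable coordinate for a flagged position.

    Length-stratified comparisons match positions by raw (chain, index);
    otherwise positions inside an annotated CDR are matched by
    (chain, region, offset-within-region), the weakest alignment assumption
    that works without numbering. Positions outside any CDR fall back to the
    raw index either way.
    """
    if by_index:
        return (chain, idx)
    reg = record.region_of(chain, idx)
    if reg is not None:
        return (chain,) + reg
    return (chain, idx)


def paratope_distance(
    rec_a: AntibodyRecord,
    rec_b: AntibodyRecord,
    prof_a: ParatopeProfile,
    prof_b: ParatopeProfile,
    length_stratified: bool = True,
) -> float:
    """1 - identity restricted to predicted-paratope residues.

    Each profile is binarized at its threshold; the union of flagged positions
    (under the positional matching above) is the denominator; positions
    flagged in both profiles with matching residues are the numerator.
    Positions flagged in only one record count as mismatches. Empty union ->
    distance 1.0 with a warning.
    """
    prof_a.validate_against(rec_a)
    prof_b.validate_against(rec_b)
    coords_a = {
        _paratope_coordinate(rec_a, c, i, length_stratified): (c, i)
        for c, i in prof_a.flagged()
    }
    coords_b = {
        _paratope_coordinate(rec_b, c, i, length_stratified): (c, i)
        for c, i in prof_b.flagged()
    }
    union = set(coords_a) | set(coords_b)
    if not union:
        logger.warning(
            "paratope_distance(%s, %s): no flagged positions in either profile",
            rec_a.record_id,
            rec_b.record_id,
        )
        return 1.0
    matches = 0
    for coord in set(coords_a) & set(coords_b):
        ca, ia = coords_a[coord]
        cb, ib = coords_b[coord]
        if rec_a.chain_seq(ca)[ia] == rec_b.chain_seq(cb)[ib]:
            matches += 1
    return 1.0 - matches / len(union)


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """C-alpha trace for one record: ``(chain, index) -> xyz`` in Angstroms."""

    record_id: str
    calpha: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def validate_against(self, record: AntibodyRecord) -> None:
        if self.record_id != record.record_id:
            raise ValidationError(
                f"structure {self.record_id} does not match record "
                f"{record.record_id}"
            )
        for (chain, idx), xyz in self.calpha.items():
            if not np.all(np.isfinite(xyz)):
                raise ValidationError(
                    f"{self.record_id}: non-finite coordinate at ({chain},{idx})"
                )
            if idx < 0 or idx >= len(record.chain_seq(chain)):
                raise ValidationError(
                    f"{self.record_id}: coordinate position ({chain},{idx}) "
                    "outside chain"
                )

    def coords_for(self, positions: Sequence[tuple[str, int]]) -> np.ndarray:
        missing = [p for p in positions if p not in self.calpha]
        if missing:
            raise ValidationError(
                f"{self.record_id}: missing C-alpha coordinates at {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        return np.asarray([self.calpha[p] for p in positions], dtype=float)


class StratificationError(ValueError):
    """Selected regions have unequal lengths; the caller must stratify."""


def _kabsch_transform(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and centroids aligning mobile onto target."""
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    return rot, cm, ct


def kabsch_rmsd(coords_a: Sequence, coords_b: Sequence) -> float:
    """Minimal C-alpha RMSD over rigid superpositions (proper rotations only).

    Textbook Kabsch: center both point sets, solve the optimal rotation by
    SVD of the covariance (with determinant correction), report the residual
    RMSD. Fewer than 3 points is computed but flagged degenerate.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] == 0:
        raise ValueError("empty coordinate lists")
    if a.shape[0] < 3:
        logger.warning("kabsch_rmsd on %d point(s): degenerate", a.shape[0])
    rot, cm, ct = _kabsch_transform(a, b)
    moved = (a - cm) @ rot.T + ct
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))


def structure_distance(
    rec_a: AntibodyRecord,
    rec_b: AntibodyRecord,
    str_a: StructureModel,
    str_b: StructureModel,
    selector: str = "cdrs_all",
    superpose_on: str | None = None,
) -> float:
    """RMSD (Angstroms) over ``selector`` after superposing on ``superpose_on``.

    Default superpose_on is the selector itself, in which case this is the
    minimal Kabsch RMSD on the selected region. With a different superposition
    region (e.g. framework/whole chain), the rigid transform fitted there is
    applied and the selector RMSD is measured without further fitting.
    Selected regions must be length-matched: structure clustering always runs
    inside length strata.
    """
    pos_a = rec_a.region_positions(selector)
    pos_b = rec_b.region_positions(selector)
    if len(pos_a) != len(pos_b):
        raise StratificationError(
            f"selected region lengths differ ({len(pos_a)} vs {len(pos_b)}); "
            "stratify by region length before structure clustering"
        )
    a_sel = str_a.coords_for(pos_a)
    b_sel = str_b.coords_for(pos_b)
    if superpose_on is None or resolve_selector(superpose_on) == resolve_selector(
        selector
    ):
        return kabsch_rmsd(a_sel, b_sel)
    sup_a = rec_a.region_positions(superpose_on)
    sup_b = rec_b.region_positions(superpose_on)
    if len(sup_a) != len(sup_b):
        raise StratificationError(
            "superposition region lengths differ; stratify by region length"
        )
    rot, cm, ct = _kabsch_transform(str_a.coords_for(sup_a), str_b.coords_for(sup_b))
    moved = (a_sel - cm) @ rot.T + ct
    return float(np.sqrt(np.mean(np.sum((moved - b_sel) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingRecord:
    """Per-residue embedding vectors for one record (fixed dimension d)."""

    record_id: str
    per_residue: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    d: int = 0

    def __post_init__(self) -> None:
        if self.per_residue and not self.d:
            self.d = len(next(iter(self.per_residue.values())))
        for pos, vec in self.per_residue.items():
            if len(vec) != self.d:
                raise ValidationError(
                    f"{self.record_id}: vector at {pos} has dimension "
                    f"{len(vec)} != {self.d}"
                )

    def pooled(self, positions: Sequence[tuple[str, int]]) -> np.ndarray:
        missing = [p for p in positions if p not in self.per_residue]
        if missing:
            raise ValidationError(
                f"{self.record_id}: missing embedding vectors at {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        return np.mean([self.per_residue[p] for p in positions], axis=0)


def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        logger.warning("zero-norm pooled embedding vector; distance set to 1.0")
        return 1.0
    return float(1.0 - np.dot(u, v) / (nu * nv))


def embedding_distance(
    emb_a: EmbeddingRecord,
    emb_b: EmbeddingRecord,
    rec_a: AntibodyRecord,
    rec_b: AntibodyRecord,
    selector: str = "all",
    metric: str = "cosine",
) -> float:
    """Distance between mean-pooled per-residue embeddings over a region.

    Vectors are arithmetic-mean pooled over the selector's positions on each
    record, then compared by cosine distance (default) or euclidean distance.
    """
    if emb_a.d != emb_b.d:
        raise ValueError(f"embedding dimension mismatch: {emb_a.d} vs {emb_b.d}")
    u = emb_a.pooled(rec_a.region_positions(selector))
    v = emb_b.pooled(rec_b.region_positions(selector))
    if metric == "cosine":
        return _cosine_distance(u, v)
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    raise ValueError(f"unknown embedding metric {metric!r}")


# ---------------------------------------------------------------------------
# Auxiliary-data ingest (delimited tables / PDB)
# ---------------------------------------------------------------------------

def read_paratope_table(path) -> dict[str, ParatopeProfile]:
    """Read paratope probabilities: TSV with record_id, chain, index, probability."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    profiles: dict[str, ParatopeProfile] = {}
    for rid, group in df.groupby("record_id", sort=False):
        probs = {
            (str(row.chain), int(row.index_)): float(row.probability)
            for row in group.rename(columns={"index": "index_"}).itertuples()
        }
        profiles[str(rid)] = ParatopeProfile(record_id=str(rid), probabilities=probs)
    return profiles


def read_embedding_table(path) -> dict[str, EmbeddingRecord]:
    """Read per-residue embeddings: TSV with record_id, chain, index, e0..e{d-1}."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    vec_cols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    vec_cols.sort(key=lambda c: int(c[1:]))
    out: dict[str, EmbeddingRecord] = {}
    for rid, group in df.groupby("record_id", sort=False):
        per_residue = {
            (str(row["chain"]), int(row["index"])): row[vec_cols].to_numpy(dtype=float)
            for _, row in group.iterrows()
        }
        out[str(rid)] = EmbeddingRecord(
            record_id=str(rid), per_residue=per_residue, d=len(vec_cols)
        )
    return out


def read_structure_pdb(
    path, record_id: str, chain_map: Mapping[str, str] | None = None
) -> StructureModel:
    """Read a C-alpha StructureModel from a PDB file.

    ``chain_map`` maps PDB chain identifiers to "heavy"/"light" (default
    H->heavy, L->light). Residues are taken in file order and mapped to
    0-based per-chain indices; only CA atoms are read.
    """
    from Bio.PDB import PDBParser

    chain_map = dict(chain_map or {"H": "heavy", "L": "light"})
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(record_id, str(path))
    calpha: dict[tuple[str, int], np.ndarray] = {}
    model = next(iter(structure))
    for pdb_chain in model:
        chain_name = chain_map.get(pdb_chain.id)
        if chain_name is None:
            continue
        idx = 0
        for residue in pdb_chain:
            if "CA" in residue:
                calpha[(chain_name, idx)] = np.asarray(
                    residue["CA"].coord, dtype=float
                )
                idx += 1
    return StructureModel(record_id=record_id, calpha=calpha)
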
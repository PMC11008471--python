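"""Synthetic paired-antibody repertoires with planted structure.

The generator emulates the statistical shape of discovery-campaign datasets:
clonally expanded lineages sharing V/J gene calls and length-matched, lightly
mutated CDR-H3s; binder labels correlated with lineage membership; per-lineage
epitope groups; structures as noisy rigid-body copies of per-lineage C-alpha
templates; per-residue embeddings as noisy per-lineage centroids on the unit
sphere; and paratope probabilities concentrated on a lineage-chosen subset of
CDR positions. Everything is deterministic under the spec seed.

Framework regions are repertoire-wide constants, so CDR identity is lower
than full-sequence identity, as in real repertoires.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repertoire import AntibodyRecord, ConfigurationError
from .similarity import EmbeddingRecord, ParatopeProfile, StructureModel

AA = "ACDEFGHIKLMNPQRSTVWY"

# repertoire-wide constant framework segments (synthetic, human-VH/VL-sized)
HEAVY_FRAMEWORKS = (
    "EVQLVESGGGLVQPGGSLRLSCAAS",   # FW1 (25)
    "WVRQAPGKGLEWVSA",             # FW2 (15)
    "RFTISRDNSKNTLYLQMNSLRAEDTAVYYC",  # FW3 (30)
    "WGQGTLVTVSS",                 # FW4 (11)
)
LIGHT_FRAMEWORKS = (
    "DIQMTQSPSSLSASVGDRVTITC",     # FW1 (23)
    "WYQQKPGKAPKLLIY",             # FW2 (15)
    "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC",  # FW3 (32)
    "FGQGTKVEIK",                  # FW4 (10)
)

DEFAULT_V_POOL = (
    "IGHV1-2*02", "IGHV1-69*01", "IGHV3-23*01", "IGHV3-30*01",
    "IGHV4-34*01", "IGHV5-51*01",
)
DEFAULT_J_POOL = ("IGHJ3*01", "IGHJ4*02", "IGHJ5*01", "IGHJ6*02")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic repertoire draw.

    ``within_lineage_mutations`` is the maximum number of length-preserving
    CDR-H3 substitutions per member; ``indel_rate`` optionally introduces
    single-residue CDR-H3 indels to exercise length stratification.
    ``structure_template_sd`` (Angstroms) sets how far lineage C-alpha
    templates deviate from the shared base trace, i.e. the between-lineage
    structural separation.
    """

    n_lineages: int = 10
    members_per_lineage: int | tuple[int, int] = 8
    v_gene_pool: Sequence[str] = DEFAULT_V_POOL
    j_gene_pool: Sequence[str] = DEFAULT_J_POOL
    cdrh3_length_range: tuple[int, int] = (10, 16)
    within_lineage_mutations: int = 1
    binder_lineage_fraction: float = 0.3
    label_noise: float = 0.0
    n_epitope_groups: int = 4
    structure_noise_sd: float = 0.1
    structure_template_sd: float = 1.5
    embedding_dim: int = 144
    embedding_noise_sd: float = 0.05
    indel_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lineages <= 0:
            raise ConfigurationError("n_lineages must be positive")
        lo = (
            self.members_per_lineage
            if isinstance(self.members_per_lineage, int)
            else self.members_per_lineage[0]
        )
        if lo <= 0:
            raise ConfigurationError("members_per_lineage must be positive")
        for name in ("binder_lineage_fraction", "label_noise", "indel_rate"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ConfigurationError(f"{name} must be in [0,1]")
        if self.embedding_dim <= 0:
            raise ConfigurationError("embedding_dim must be positive")
        if self.within_lineage_mutations >= self.cdrh3_length_range[0]:
            raise ConfigurationError(
                "within_lineage_mutations must be smaller than the shortest "
                "CDR-H3"
            )


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # independent substream per generator so adding one generator never
    # perturbs another
    return np.random.default_rng([spec.seed, stream])


def _stable_hash(obj) -> int:
    # process-independent (unlike builtin hash, which is salted)
    return zlib.crc32(repr(obj).encode())


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    chars = list(seq)
    if n_mut == 0:
        return seq
    positions = rng.choice(len(chars), size=n_mut, replace=False)
    for pos in positions:
        alternatives = [a for a in AA if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


@dataclass
class Lineage:
    lineage_id: str
    v_call: str
    j_call: str
    cdrs: dict[str, str]
    binder: bool
    epitope: str


def _draw_lineages(spec: FixtureSpec, rng: np.random.Generator) -> list[Lineage]:
    n_binder = round(spec.binder_lineage_fraction * spec.n_lineages)
    binder_idx = set(
        rng.choice(spec.n_lineages, size=n_binder, replace=False).tolist()
    )
    lineages = []
    for l in range(spec.n_lineages):
        lo, hi = spec.cdrh3_length_range
        cdrh3_len = int(rng.integers(lo, hi + 1))
        cdrs = {
            "cdrh1": _random_seq(rng, 8),
            "cdrh2": _random_seq(rng, 8),
            "cdrh3": _random_seq(rng, cdrh3_len),
            "cdrl1": _random_seq(rng, 6),
            "cdrl2": _random_seq(rng, 3),
            "cdrl3": _random_seq(rng, 9),
        }
        lineages.append(
            Lineage(
                lineage_id=f"L{l:02d}",
                v_call=str(rng.choice(list(spec.v_gene_pool))),
                j_call=str(rng.choice(list(spec.j_gene_pool))),
                cdrs=cdrs,
                binder=l in binder_idx,
                epitope=f"e{int(rng.integers(spec.n_epitope_groups))}",
            )
        )
    return lineages


def _assemble(frameworks, cdr_names, cdrs) -> tuple[str, dict[str, tuple[int, int]]]:
    seq = ""
    bounds = {}
    for fw, name in zip(frameworks, cdr_names + (None,)):
        seq += fw
        if name is not None:
            bounds[name] = (len(seq), len(seq) + len(cdrs[name]))
            seq += cdrs[name]
    return seq, bounds


def make_repertoire(
    spec: FixtureSpec,
) -> tuple[list[AntibodyRecord], pd.DataFrame]:
    """Generate records plus the planted truth table.

    Returns ``(records, truth)`` where truth has columns record_id,
    lineage_id, binder, epitope. Records carry the same labels (the truth
    table is the label-free pipeline's answer key).
    """
    spec.validate()
    rng = _rng(spec, 0)
    lineages = _draw_lineages(spec, rng)
    records: list[AntibodyRecord] = []
    rows = []
    for lin in lineages:
        if isinstance(spec.members_per_lineage, int):
            n_members = spec.members_per_lineage
        else:
            lo, hi = spec.members_per_lineage
            n_members = int(rng.integers(lo, hi + 1))
        for m in range(n_members):
            cdrs = dict(lin.cdrs)
            n_mut = int(rng.integers(0, spec.within_lineage_mutations + 1))
            cdrh3 = _mutate(rng, cdrs["cdrh3"], n_mut)
            if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
                if rng.random() < 0.5 and len(cdrh3) > 3:
                    pos = int(rng.integers(len(cdrh3)))
                    cdrh3 = cdrh3[:pos] + cdrh3[pos + 1 :]
                else:
                    pos = int(rng.integers(len(cdrh3) + 1))
                    cdrh3 = cdrh3[:pos] + _random_seq(rng, 1) + cdrh3[pos:]
            cdrs["cdrh3"] = cdrh3
            heavy, h_bounds = _assemble(
                HEAVY_FRAMEWORKS, ("cdrh1", "cdrh2", "cdrh3"), cdrs
            )
            light, l_bounds = _assemble(
                LIGHT_FRAMEWORKS, ("cdrl1", "cdrl2", "cdrl3"), cdrs
            )
            binder = lin.binder
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                binder = not binder
            rec = AntibodyRecord(
                record_id=f"{lin.lineage_id}M{m:02d}",
                heavy_seq=heavy,
                light_seq=light,
                v_call=lin.v_call,
                j_call=lin.j_call,
                region_bounds={**h_bounds, **l_bounds},
                binder_label=binder,
                epitope_label=lin.epitope,
                lineage_id=lin.lineage_id,
            )
            rec.validate()
            records.append(rec)
            rows.append(
                {
                    "record_id": rec.record_id,
                    "lineage_id": lin.lineage_id,
                    "binder": binder,
                    "epitope": lin.epitope,
                }
            )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _base_trace(n: int) -> np.ndarray:
    """Deterministic helix-like C-alpha curve of n points (3.8 A spacing-ish)."""
    i = np.arange(n)
    return np.column_stack(
        [2.3 * np.cos(i * 100.0 * np.pi / 180.0),
         2.3 * np.sin(i * 100.0 * np.pi / 180.0),
         1.5 * i]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    w, x, y, z = quat
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_structures(
    records: Sequence[AntibodyRecord], spec: FixtureSpec
) -> dict[str, StructureModel]:
    """Noisy rigid-body copies of per-lineage C-alpha templates.

    Each lineage's template is the shared base trace plus a lineage-specific
    displacement field (sd = structure_template_sd); members add isotropic
    Gaussian noise (sd = structure_noise_sd) and a random rigid motion, which
    Kabsch superposition removes exactly.
    """
    spec.validate()
    rng = _rng(spec, 1)
    # templates are drawn per (lineage, chain-length signature) so indel
    # variants still get a same-length trace
    templates: dict[tuple, np.ndarray] = {}
    out: dict[str, StructureModel] = {}
    for rec in records:
        positions = [("light", i) for i in range(len(rec.light_seq))] + [
            ("heavy", i) for i in range(len(rec.heavy_seq))
        ]
        n = len(positions)
        key = (rec.lineage_id, n)
        if key not in templates:
            templates[key] = _base_trace(n) + _rng(
                spec, _stable_hash(key) % (2**31)
            ).normal(scale=spec.structure_template_sd, size=(n, 3))
        coords = templates[key] + rng.normal(
            scale=spec.structure_noise_sd, size=(n, 3)
        )
        rot = _random_rotation(rng)
        trans = rng.uniform(-20.0, 20.0, size=3)
        coords = coords @ rot.T + trans
        out[rec.record_id] = StructureModel(
            record_id=rec.record_id,
            calpha={pos: coords[k] for k, pos in enumerate(positions)},
        )
    return out


# ---------------------------------------------------------------------------
# Embeddings and paratopes
# ---------------------------------------------------------------------------

def make_embeddings(
    records: Sequence[AntibodyRecord],
    spec: FixtureSpec,
    centroid_of: Mapping[str, str] | None = None,
) -> dict[str, EmbeddingRecord]:
    """Per-residue embeddings around per-lineage unit-sphere centroids.

    ``centroid_of`` optionally maps lineage_id -> centroid group so two
    lineages can be forced to share a centroid (for orthogonality fixtures);
    default is one centroid per lineage.
    """
    spec.validate()
    rng = _rng(spec, 2)
    lineage_ids = sorted({rec.lineage_id or rec.record_id for rec in records})
    groups = {
        lid: (centroid_of or {}).get(lid, lid) for lid in lineage_ids
    }
    centroids: dict[str, np.ndarray] = {}
    for group in sorted(set(groups.values())):
        vec = _rng(spec, 2**22 + _stable_hash(group) % (2**20)).normal(
            size=spec.embedding_dim
        )
        centroids[group] = vec / np.linalg.norm(vec)
    out: dict[str, EmbeddingRecord] = {}
    for rec in records:
        centroid = centroids[groups[rec.lineage_id or rec.record_id]]
        per_residue: dict[tuple[str, int], np.ndarray] = {}
        for chain, seq in (("light", rec.light_seq), ("heavy", rec.heavy_seq)):
            noise = rng.normal(
                scale=spec.embedding_noise_sd, size=(len(seq), spec.embedding_dim)
            )
            for i in range(len(seq)):
                per_residue[(chain, i)] = centroid + noise[i]
        out[rec.record_id] = EmbeddingRecord(
            record_id=rec.record_id, per_residue=per_residue, d=spec.embedding_dim
        )
    return out


def make_paratopes(
    records: Sequence[AntibodyRecord],
    spec: FixtureSpec,
    jitter: float = 0.1,
) -> dict[str, ParatopeProfile]:
    """Paratope probabilities concentrated on a lineage-chosen CDR subset.

    Each lineage flags a subset of CDR-H3 and CDR-L3 offsets; flagged
    positions get probabilities in [1 - jitter - eps, 1), unflagged CDR
    positions in (0, jitter + eps]; binarization at 0.5 recovers the planted
    subset exactly whenever jitter < 0.5.
    """
    spec.validate()
    if not (0.0 <= jitter < 0.5):
        raise ConfigurationError("jitter must be in [0, 0.5)")
    rng = _rng(spec, 3)
    # planted flag offsets per lineage, chosen on region offsets so every
    # length-matched member shares them
    planted: dict[str, dict[str, set[int]]] = {}
    out: dict[str, ParatopeProfile] = {}
    for rec in records:
        lid = rec.lineage_id or rec.record_id
        if lid not in planted:
            lrng = _rng(spec, 2**23 + _stable_hash(lid) % (2**20))
            h3_len = rec.region_bounds["cdrh3"][1] - rec.region_bounds["cdrh3"][0]
            l3_len = rec.region_bounds["cdrl3"][1] - rec.region_bounds["cdrl3"][0]
            n_h3 = max(2, int(round(0.6 * h3_len)))
            n_l3 = max(1, int(round(0.4 * l3_len)))
            planted[lid] = {
                "cdrh3": set(
                    lrng.choice(h3_len, size=min(n_h3, h3_len), replace=False).tolist()
                ),
                "cdrl3": set(
                    lrng.choice(l3_len, size=min(n_l3, l3_len), replace=False).tolist()
                ),
            }
        probs: dict[tuple[str, int], float] = {}
        for region, chain in (("cdrh3", "heavy"), ("cdrl3", "light")):
            start, end = rec.region_bounds[region]
            for offset in range(end - start):
                flagged = offset in planted[lid][region]
                if flagged:
                    p = 1.0 - jitter * rng.random()
                else:
                    p = jitter * rng.random()
                probs[(chain, start + offset)] = float(p)
        out[rec.record_id] = ParatopeProfile(record_id=rec.record_id, probabilities=probs)
    return out


# ---------------------------------------------------------------------------
# On-disk fixture writers (used by the simulate subcommand)
# ---------------------------------------------------------------------------

def write_paratope_table(profiles: Mapping[str, ParatopeProfile], path) -> None:
    rows = [
        {"record_id": rid, "chain": chain, "index": idx, "probability": round(p, 6)}
        for rid, prof in sorted(profiles.items())
        for (chain, idx), p in sorted(prof.probabilities.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_embedding_table(embeddings: Mapping[str, EmbeddingRecord], path) -> None:
    d = next(iter(embeddings.values())).d
    cols = ["record_id", "chain", "index"] + [f"e{k}" for k in range(d)]
    rows = []
    for rid, emb in sorted(embeddings.items()):
        for (chain, idx), vec in sorted(emb.per_residue.items()):
            rows.append([rid, chain, idx] + [float(f"{v:.6g}") for v in vec])
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_structure_pdb(
    model: StructureModel, record: AntibodyRecord, path
) -> None:
    """Write a C-alpha-only PDB (chains H and L) for one record."""
    from Bio.PDB import StructureBuilder, PDBIO
    from Bio.SeqUtils import seq3

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure(record.record_id)
    builder.init_model(0)
    for chain_name, pdb_id, seq in (
        ("heavy", "H", record.heavy_seq),
        ("light", "L", record.light_seq),
    ):
        if not seq:
            continue
        builder.init_chain(pdb_id)
        builder.init_seg("    ")
        for i, aa in enumerate(seq):
            builder.init_residue(seq3(aa).upper(), " ", i + 1, " ")
            xyz = model.calpha[(chain_name, i)]
            builder.init_atom(
                "CA", np.asarray(xyz, dtype=float), 0.0, 1.0, " ", " CA ", element="C"
            )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
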
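"""Antibody records, region vocabulary, and stratification keys.

Records are paired heavy/light amino-acid sequences with V/J gene calls and
explicit IMGT CDR boundaries. Region boundaries are consumed, not computed:
annotation (IMGT numbering, CDR calling) is delegated to upstream tools or to
the synthetic repertoire generator. All intervals are 0-based, half-open, on
the owning chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("abclust")

#: canonical region names, light chain first, numeric order within each chain
CDR_REGIONS = ("cdrl1", "cdrl2", "cdrl3", "cdrh1", "cdrh2", "cdrh3")

HEAVY_REGIONS = frozenset({"cdrh1", "cdrh2", "cdrh3"})
LIGHT_REGIONS = frozenset({"cdrl1", "cdrl2", "cdrl3"})

#: region selectors: name -> tuple of parts, where a part is either a CDR
#: region name or a whole chain ("heavy"/"light"). Concatenation order is
#: fixed here and used everywhere (l3_h3 is CDR-L3 then CDR-H3; cdrs_all is
#: all six CDRs light-then-heavy in numeric order; "all" is light then heavy
#: chain).
REGION_SELECTORS: dict[str, tuple[str, ...]] = {
    "cdrh3": ("cdrh3",),
    "cdrl3": ("cdrl3",),
    "l3_h3": ("cdrl3", "cdrh3"),
    "cdrh": ("cdrh1", "cdrh2", "cdrh3"),
    "cdrs_all": CDR_REGIONS,
    "heavy": ("heavy",),
    "light": ("light",),
    "all": ("light", "heavy"),
}

#: aliases seen in published parameter tables
SELECTOR_ALIASES = {"all_cdr": "cdrs_all", "cdrh_all": "cdrh", "cdrhs_all": "cdrh"}


class AnnotationError(ValueError):
    """A record lacks a region/chain required by the requested operation."""


class ValidationError(ValueError):
    """Input data violates a record or repertoire invariant."""


class ConfigurationError(ValueError):
    """A configuration (column map, scheme, method config) is invalid."""


def resolve_selector(name: str) -> tuple[str, ...]:
    """Return the ordered parts of a region selector, resolving aliases."""
    name = SELECTOR_ALIASES.get(name, name)
    try:
        return REGION_SELECTORS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown region selector {name!r}; known: {sorted(REGION_SELECTORS)}"
        ) from None


@dataclass
class AntibodyRecord:
    """One paired (or heavy-only) antibody with sequences and annotation.

    ``region_bounds`` maps region names (cdrh1..cdrh3, cdrl1..cdrl3) to
    0-based half-open ``(start, end)`` intervals on the owning chain.
    ``lineage_id`` is fixture provenance only and never read by any
    similarity or clustering code.
    """

    record_id: str
    heavy_seq: str
    light_seq: str = ""
    v_call: str = ""
    j_call: str = ""
    region_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)
    binder_label: bool | None = None
    epitope_label: str | None = None
    lineage_id: str | None = None

    def validate(self) -> None:
        for region, (start, end) in self.region_bounds.items():
            if region not in HEAVY_REGIONS and region not in LIGHT_REGIONS:
                raise ValidationError(
                    f"{self.record_id}: unknown region {region!r}"
                )
            chain = self.heavy_seq if region in HEAVY_REGIONS else self.light_seq
            if not (0 <= start <= end <= len(chain)):
                raise ValidationError(
                    f"{self.record_id}: region {region} interval [{start}, {end}) "
                    f"outside chain of length {len(chain)}"
                )

    def chain_seq(self, chain: str) -> str:
        if chain == "heavy":
            return self.heavy_seq
        if chain == "light":
            return self.light_seq
        raise ValueError(f"unknown chain {chain!r}")

    def region_positions(self, selector: str) -> list[tuple[str, int]]:
        """Ordered ``(chain, index)`` positions covered by ``selector``."""
        positions: list[tuple[str, int]] = []
        for part in resolve_selector(selector):
            if part in ("heavy", "light"):
                seq = self.chain_seq(part)
                if part == "light" and not seq:
                    raise AnnotationError(
                        f"{self.record_id}: selector requires light chain but "
                        "light_seq is empty"
                    )
                positions.extend((part, i) for i in range(len(seq)))
            else:
                chain = "heavy" if part in HEAVY_REGIONS else "light"
                if chain == "light" and not self.light_seq:
                    raise AnnotationError(
                        f"{self.record_id}: selector requires light-chain region "
                        f"{part} but light_seq is empty"
                    )
                if part not in self.region_bounds:
                    raise AnnotationError(
                        f"{self.record_id}: region {part} not annotated"
                    )
                start, end = self.region_bounds[part]
                positions.extend((chain, i) for i in range(start, end))
        return positions

    def region_of(self, chain: str, index: int) -> tuple[str, int] | None:
        """Map a chain position to ``(region, offset)`` if inside a CDR."""
        wanted = HEAVY_REGIONS if chain == "heavy" else LIGHT_REGIONS
        for region in self.region_bounds:
            if region in wanted:
                start, end = self.region_bounds[region]
                if start <= index < end:
                    return region, index - start
        return None


def extract_region(record: AntibodyRecord, selector: str) -> str:
    """Concatenated residues of the selected regions in canonical order."""
    return "".join(
        record.chain_seq(chain)[idx] for chain, idx in record.region_positions(selector)
    )


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

def normalize_gene(call: str) -> str:
    """Strip the allele suffix from a gene call (IGHV3-23*01 -> IGHV3-23)."""
    return call.split("*", 1)[0].strip()


@dataclass(frozen=True)
class Stratification:
    """A stratification scheme: group records before any distance is computed.

    ``genes`` is None, "v" or "vj" (heavy-chain calls, allele-stripped by
    default); ``length_of`` is a region-selector name whose per-region lengths
    form part of the key. The scheme "none" is Stratification().
    """

    genes: str | None = None
    length_of: str | None = None
    strip_alleles: bool = True

    @classmethod
    def parse(cls, text: str | None) -> "Stratification":
        """Parse 'none', 'length:cdrh3', 'genes:v', 'genes:vj+length:cdrh3'."""
        if text is None or text == "" or text == "none":
            return cls()
        genes = None
        length_of = None
        for part in text.split("+"):
            kind, _, value = part.partition(":")
            if kind == "length":
                length_of = value or "cdrh3"
            elif kind == "genes":
                if value not in ("v", "vj"):
                    raise ConfigurationError(f"unknown gene scheme {value!r}")
                genes = value
            else:
                raise ConfigurationError(f"unknown stratification part {part!r}")
        return cls(genes=genes, length_of=length_of)

    def __str__(self) -> str:
        parts = []
        if self.genes:
            parts.append(f"genes:{self.genes}")
        if self.length_of:
            parts.append(f"length:{self.length_of}")
        return "+".join(parts) or "none"


def strat_key(record: AntibodyRecord, scheme: Stratification) -> tuple:
    """Hashable stratum key for a record under a stratification scheme.

    Records with equal keys belong to the same stratum; the scheme "none"
    returns a constant key, so "same key" always partitions a repertoire.
    """
    key: list = []
    if scheme.genes is not None:
        v = normalize_gene(record.v_call) if scheme.strip_alleles else record.v_call
        key.append(v)
        if scheme.genes == "vj":
            j = normalize_gene(record.j_call) if scheme.strip_alleles else record.j_call
            key.append(j)
    if scheme.length_of is not None:
        for part in resolve_selector(scheme.length_of):
            if part in ("heavy", "light"):
                key.append(len(record.chain_seq(part)))
            else:
                if part not in record.region_bounds:
                    raise AnnotationError(
                        f"{record.record_id}: stratification needs region {part}"
                    )
                start, end = record.region_bounds[part]
                key.append(end - start)
    return tuple(key)


# ---------------------------------------------------------------------------
# AIRR-style TSV ingest / echo
# ---------------------------------------------------------------------------

#: default column names (AIRR Rearrangement flavored; one paired record per row)
DEFAULT_COLUMNS = {
    "record_id": "sequence_id",
    "heavy_seq": "sequence_aa",
    "light_seq": "sequence_aa_light",
    "v_call": "v_call",
    "j_call": "j_call",
    "binder_label": "binder_label",
    "epitope_label": "epitope_label",
    "lineage_id": "lineage_id",
}

REQUIRED_FIELDS = ("record_id", "heavy_seq", "v_call", "j_call")


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "t", "1", "yes"):
        return True
    if text in ("false", "f", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean label {value!r}")


def read_airr_table(
    path, column_map: Mapping[str, str] | None = None
) -> list[AntibodyRecord]:
    """Read an AIRR-rearrangement-flavored TSV of paired antibody records.

    Region intervals come from ``<region>_start`` / ``<region>_end`` columns
    (0-based, half-open). Rows failing per-row validation are reported via the
    package logger and skipped; duplicate ids or missing required columns
    raise.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field_name in REQUIRED_FIELDS:
        if columns[field_name] not in df.columns:
            raise ConfigurationError(
                f"required column {columns[field_name]!r} (for {field_name}) "
                f"missing from {path}"
            )
    if f"cdrh3_start" not in df.columns or f"cdrh3_end" not in df.columns:
        raise ConfigurationError(
            f"required columns 'cdrh3_start'/'cdrh3_end' missing from {path}"
        )
    ids = df[columns["record_id"]]
    dups = sorted(ids[ids.duplicated()].unique())
    if dups:
        raise ValidationError(f"duplicate record ids: {dups}")

    records: list[AntibodyRecord] = []
    for _, row in df.iterrows():
        rid = row[columns["record_id"]]
        bounds: dict[str, tuple[int, int]] = {}
        for region in CDR_REGIONS:
            s_col, e_col = f"{region}_start", f"{region}_end"
            if s_col in df.columns and e_col in df.columns:
                s, e = row[s_col], row[e_col]
                if s != "" and e != "":
                    bounds[region] = (int(s), int(e))
        rec = AntibodyRecord(
            record_id=rid,
            heavy_seq=row[columns["heavy_seq"]],
            light_seq=row.get(columns["light_seq"], ""),
            v_call=row[columns["v_call"]],
            j_call=row[columns["j_call"]],
            region_bounds=bounds,
            binder_label=_parse_bool(row.get(columns["binder_label"])),
            epitope_label=(row.get(columns["epitope_label"]) or None),
            lineage_id=(row.get(columns["lineage_id"]) or None),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            logger.warning("dropping invalid row: %s", exc)
            continue
        records.append(rec)
    return records


def write_airr_table(records: Iterable[AntibodyRecord], path) -> None:
    """Echo records to the same TSV dialect read_airr_table consumes."""
    rows = []
    for rec in records:
        row: dict = {
            "sequence_id": rec.record_id,
            "sequence_aa": rec.heavy_seq,
            "sequence_aa_light": rec.light_seq,
            "v_call": rec.v_call,
            "j_call": rec.j_call,
            "binder_label": "" if rec.binder_label is None else str(rec.binder_label),
            "epitope_label": rec.epitope_label or "",
            "lineage_id": rec.lineage_id or "",
        }
        for region in CDR_REGIONS:
            if region in rec.region_bounds:
                row[f"{region}_start"], row[f"{region}_end"] = rec.region_bounds[region]
            else:
                row[f"{region}_start"] = row[f"{region}_end"] = ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def check_unique_ids(records: Sequence[AntibodyRecord]) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for rec in records:
        if rec.record_id in seen:
            dups.append(rec.record_id)
        seen.add(rec.record_id)
    if dups:
        raise ValidationError(f"duplicate record ids: {sorted(set(dups))}")
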
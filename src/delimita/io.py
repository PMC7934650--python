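"""Readers and writers for the pipeline's standard formats.

Three inputs drive everything downstream: a specimen-level morphometric
table (one row per worker, 16 linear head/mesosoma/waist measurements in
micrometres plus a collection-event "nest" code), a fixed-length COI
alignment in FASTA, and an optional rooted tree in Newick.  The trait
registry is closed: the 16 measurement codes are fixed, and an input
column pretending to be a 17th trait is an error, never silently ignored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Structurally malformed input (missing column, ragged alignment...)."""


class ValidationError(ValueError):
    """Well-formed input carrying an impossible value (e.g. CWb <= 0)."""


@dataclass(frozen=True)
class TraitSpec:
    """One registered morphometric character.

    ``magnification`` is the stereomicroscope setting the measurement is
    taken at; it is metadata only and never enters any computation.
    """

    code: str
    description: str
    magnification: int

    def __post_init__(self) -> None:
        if self.magnification not in (25, 50, 100):
            raise ValueError(f"magnification must be 25, 50 or 100, got {self.magnification}")


#: The closed registry of the 16 continuous worker traits (all in um).
TRAIT_REGISTRY: dict[str, TraitSpec] = {
    t.code: t
    for t in (
        TraitSpec("CL", "maximum median length of head capsule", 50),
        TraitSpec("CWb", "maximum width of head capsule in full-face view", 50),
        TraitSpec("EL", "maximum diameter of compound eye", 100),
        TraitSpec("FL", "maximum width of frontal lobes", 100),
        TraitSpec("FRS", "frontal carina distance", 100),
        TraitSpec("ML", "diagonal length of alitrunk in profile", 25),
        TraitSpec("MW", "maximum width of pronotum", 100),
        TraitSpec("NOH", "petiole node height", 100),
        TraitSpec("PEL", "petiole length", 100),
        TraitSpec("PEW", "maximum petiole width, dorsal view", 100),
        TraitSpec("PoOC", "postocular distance", 50),
        TraitSpec("PPH", "maximum postpetiole height, lateral view", 100),
        TraitSpec("PPW", "maximum postpetiole width, dorsal view", 100),
        TraitSpec("SL", "maximum straight-line scape length", 25),
        TraitSpec("SPST", "propodeal spine length from stigma centre", 100),
        TraitSpec("SPTI", "distance between propodeal spine tips, dorsal view", 100),
    )
}

TRAIT_CODES: tuple[str, ...] = tuple(TRAIT_REGISTRY)

# Case-insensitive lookup; "POOC" and "PoOC" are the same character (the
# literature uses both spellings).
_CANON = {c.upper(): c for c in TRAIT_CODES}


def canonical_trait(code: str) -> str:
    """Map a (case-insensitive) trait code to its registry spelling.

    Raises :class:`FormatError` for codes outside the closed registry.
    """
    canon = _CANON.get(code.strip().upper())
    if canon is None:
        raise FormatError(f"unknown trait code {code!r}; registry has exactly {TRAIT_CODES}")
    return canon


class TypeStatus(enum.Enum):
    NONE = "none"
    HOLOTYPE = "holotype"
    SYNTYPE = "syntype"
    PARATYPE = "paratype"


@dataclass
class SpecimenRecord:
    """One measured worker: traits in um plus collection metadata."""

    specimen_id: str
    nest_code: str
    traits: dict[str, float]
    qualitative_label: str | None = None
    type_status: TypeStatus = TypeStatus.NONE
    type_series_id: str | None = None
    metadata: dict[str, object] = field(default_factory=dict)

    def validate(self, require_all: bool = True) -> None:
        if not self.nest_code:
            raise ValidationError(f"{self.specimen_id}: empty nest_code")
        for code, value in self.traits.items():
            canonical_trait(code)
            if value is not None and value <= 0:
                raise ValidationError(f"{self.specimen_id}: trait {code} = {value} (must be > 0)")
        if require_all:
            missing = [c for c in TRAIT_CODES if self.traits.get(c) is None]
            if missing:
                raise ValidationError(f"{self.specimen_id}: missing traits {missing}")


@dataclass
class MorphoMatrix:
    """Rectangular specimen x trait table with nest codes and labels."""

    records: list[SpecimenRecord]
    trait_order: tuple[str, ...] = TRAIT_CODES

    def __len__(self) -> int:
        return len(self.records)

    @property
    def nest_codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.nest_code)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {"specimen_id": r.specimen_id, "nest_code": r.nest_code}
            row.update({c: r.traits.get(c) for c in self.trait_order})
            row["qualitative_label"] = r.qualitative_label
            row["type_status"] = r.type_status.value
            row["type_series_id"] = r.type_series_id
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, keep: Iterable[str]) -> "MorphoMatrix":
        keep = set(keep)
        return MorphoMatrix([r for r in self.records if r.specimen_id in keep], self.trait_order)


_MANDATORY = ("specimen_id", "nest_code")
_OPTIONAL = ("qualitative_label", "type_status", "type_series_id")


def read_morpho_table(
    path: str | Path,
    dialect: str = "auto",
    column_map: Mapping[str, str] | None = None,
) -> MorphoMatrix:
    """Read a specimen-level trait table (CSV or TSV).

    The header must carry ``specimen_id``, ``nest_code`` and the 16 trait
    codes (case-insensitive; a ``column_map`` of ``file column -> canonical
    name`` accommodates spreadsheet-export variants).  Unknown columns are
    kept as opaque per-specimen metadata.  Values are micrometres.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))

    rename: dict[str, str] = {}
    for col in df.columns:
        low = str(col).strip()
        if low.lower() in [m.lower() for m in _MANDATORY + _OPTIONAL]:
            rename[col] = low.lower()
        elif low.upper() in _CANON:
            rename[col] = _CANON[low.upper()]
    df = df.rename(columns=rename)

    for col in _MANDATORY:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    missing_traits = [c for c in TRAIT_CODES if c not in df.columns]
    if missing_traits:
        raise FormatError(f"missing trait column(s) {missing_traits}")

    known = set(_MANDATORY) | set(_OPTIONAL) | set(TRAIT_CODES)
    extra = [c for c in df.columns if c not in known]

    records: list[SpecimenRecord] = []
    for _, row in df.iterrows():
        traits = {c: float(row[c]) if pd.notna(row[c]) else None for c in TRAIT_CODES}
        status = TypeStatus.NONE
        if "type_status" in df.columns and pd.notna(row.get("type_status")):
            raw = str(row["type_status"]).strip().lower()
            status = TypeStatus(raw) if raw else TypeStatus.NONE
        rec = SpecimenRecord(
            specimen_id=str(row["specimen_id"]),
            nest_code=str(row["nest_code"]),
            traits=traits,
            qualitative_label=(
                str(row["qualitative_label"])
                if "qualitative_label" in df.columns and pd.notna(row.get("qualitative_label"))
                else None
            ),
            type_status=status,
            type_series_id=(
                str(row["type_series_id"])
                if "type_series_id" in df.columns and pd.notna(row.get("type_series_id"))
                else None
            ),
            metadata={c: row[c] for c in extra},
        )
        rec.validate(require_all=False)
        records.append(rec)
    return MorphoMatrix(records)


def write_morpho_table(m: MorphoMatrix, path: str | Path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    m.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# sequences


class Role(enum.Enum):
    INGROUP = "ingroup"
    OUTGROUP = "outgroup"


@dataclass
class SequenceRecord:
    seq_id: str
    residues: str
    role: Role = Role.INGROUP

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - set("ACGT-N")
        if bad:
            raise ValidationError(f"{self.seq_id}: illegal residues {sorted(bad)}")


@dataclass
class Alignment:
    """Equal-length sequences; columns are 1-based in every report."""

    sequences: list[SequenceRecord]

    def __post_init__(self) -> None:
        ids = [s.seq_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids {dup}")
        lengths = {len(s.residues) for s in self.sequences}
        if len(lengths) > 1:
            ragged = [s.seq_id for s in self.sequences if len(s.residues) != len(self.sequences[0].residues)]
            raise FormatError(f"ragged alignment; offending ids include {ragged}")

    @property
    def length(self) -> int:
        return len(self.sequences[0].residues) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.seq_id for s in self.sequences]

    def ingroup(self) -> "Alignment":
        return Alignment([s for s in self.sequences if s.role is Role.INGROUP])


def read_fasta_alignment(path: str | Path, outgroup_ids: Sequence[str] = ()) -> Alignment:
    """Read an aligned FASTA; lowercase is normalized to uppercase."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty FASTA")
    og = set(outgroup_ids)
    seqs = [
        SequenceRecord(r.id, str(r.seq), Role.OUTGROUP if r.id in og else Role.INGROUP)
        for r in records
    ]
    return Alignment(seqs)


def write_fasta_alignment(a: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in a.sequences:
            fh.write(f">{s.seq_id}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# trees


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree (from a path, or a literal Newick string).

    Leaf labels must be unique; parse problems raise :class:`FormatError`.
    """
    if isinstance(source, Path):
        text = source.read_text()
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels {dup}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]
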
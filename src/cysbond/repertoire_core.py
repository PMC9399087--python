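"""Data model and I/O for immune-repertoire clone tables.

A *clone* is a unique combination of V gene and CDR3 nucleotide sequence
within one sample; a *clonotype* is a unique combination of V gene and CDR3
amino-acid sequence.  Clone tables travel as AIRR Rearrangement TSV
(columns ``v_call``, ``junction``, ``junction_aa``, ``duplicate_count``,
``productive``), the community standard for rearrangement-level repertoire
data.  Downstream statistics count each clone once per sample regardless of
its read support, so ``detection_count`` is carried only for filtering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, NamedTuple

import pandas as pd

logger = logging.getLogger("cysbond")

#: Amino acids encoded by the standard genetic code (no stop).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: One representative codon per amino acid plus alternatives, used for
#: seeded back-translation in the synthetic generator.
CODON_TABLE: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    "*": ("TAA", "TAG", "TGA"),
    "X": ("NNN",),
}

_STANDARD_CODON_TO_AA = {
    codon: aa for aa, codons in CODON_TABLE.items() for codon in codons
}


class Chain(str, Enum):
    """TCR chain identity."""

    alpha = "alpha"
    beta = "beta"


class Lineage(str, Enum):
    """T-cell lineage labels used throughout the study design."""

    preselection = "preselection"
    CD4_Tconv = "CD4_Tconv"
    CD8_Tconv = "CD8_Tconv"
    Treg = "Treg"
    TypeA_IELp_CD8aaIEL = "TypeA_IELp_CD8aaIEL"
    other = "other"


class FormatError(ValueError):
    """Input file violates the expected AIRR Rearrangement layout."""


class EmptySampleError(ValueError):
    """A sample contains no clones where at least one is required."""


class DegenerateJunctionError(ValueError):
    """Junction too short to contain a CDR3 between its conserved flanks."""


def normalize_v_gene(v_call: str) -> str:
    """Normalize a ``v_call`` value to a bare gene symbol.

    Strips allele suffixes (``*01``) and a leading ``mouse `` prefix, so
    clones are keyed on the gene, not the allele.
    """
    name = v_call.strip()
    name = re.sub(r"^mouse\s+", "", name, flags=re.IGNORECASE)
    name = name.split("*", 1)[0]
    return name.strip()


def chain_of_v_gene(v_gene: str) -> Chain:
    """Infer the chain from the V gene symbol (TRAV->alpha, TRBV->beta)."""
    sym = v_gene.upper()
    if sym.startswith(("TRAV", "TRA")):
        return Chain.alpha
    if sym.startswith(("TRBV", "TRB")):
        return Chain.beta
    raise ValueError(f"cannot infer chain from V gene {v_gene!r}")


def extract_cdr3_imgt(junction_aa: str) -> str:
    """Return the CDR3-IMGT: the junction minus its conserved flanks.

    The junction includes the conserved N-terminal Cys and C-terminal
    Trp/Phe; CDR3-IMGT excludes both, so the first and last residues are
    removed.  Raises :class:`DegenerateJunctionError` for junctions shorter
    than 3 residues.
    """
    if len(junction_aa) < 3:
        raise DegenerateJunctionError(
            f"junction {junction_aa!r} shorter than 3 aa has no CDR3-IMGT"
        )
    return junction_aa[1:-1]


def translate_nt(nt: str) -> str:
    """Translate a nucleotide string codon-by-codon (standard code)."""
    return "".join(
        _STANDARD_CODON_TO_AA.get(nt[i : i + 3].upper(), "X")
        for i in range(0, len(nt) - len(nt) % 3, 3)
    )


@dataclass(frozen=True, order=True)
class CloneRecord:
    """One V-gene + CDR3-nucleotide clone observed in one sample."""

    v_gene: str
    chain: Chain
    cdr3_nt: str
    junction_aa: str
    cdr3_aa: str
    detection_count: int
    productive: bool = True

    def __post_init__(self) -> None:
        if self.detection_count < 1:
            raise ValueError("detection_count must be >= 1")
        if len(self.junction_aa) >= 3 and len(self.cdr3_aa) != len(self.junction_aa) - 2:
            raise ValueError(
                "cdr3_aa must be junction_aa without its two conserved flanks"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Clone identity: (V gene, CDR3 nucleotide sequence)."""
        return (self.v_gene, self.cdr3_nt)

    @property
    def clonotype(self) -> "Clonotype":
        return Clonotype(self.v_gene, self.cdr3_aa)


class Clonotype(NamedTuple):
    """Amino-acid-level receptor identity: (V gene, CDR3 amino acids)."""

    v_gene: str
    cdr3_aa: str


@dataclass
class RepertoireSample:
    """A set of clones from one sorted cell sample, with metadata."""

    sample_id: str
    clones: list[CloneRecord] = field(default_factory=list)
    chain: Chain | None = None
    lineage: Lineage = Lineage.other
    genotype: str = "wild_type"

    def __post_init__(self) -> None:
        keys = [c.key for c in self.clones]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (v_gene, cdr3_nt) clone keys in sample")

    def __len__(self) -> int:
        return len(self.clones)

    def clone_set(self) -> frozenset[CloneRecord]:
        return frozenset(self.clones)


def make_clone(
    v_call: str,
    junction_nt: str,
    junction_aa: str,
    detection_count: int = 1,
    productive: bool | None = None,
) -> CloneRecord:
    """Build a :class:`CloneRecord` from raw rearrangement fields.

    ``productive`` defaults to an in-frame, stop-free check on the junction.
    """
    v_gene = normalize_v_gene(v_call)
    if productive is None:
        productive = len(junction_nt) % 3 == 0 and "*" not in junction_aa
    return CloneRecord(
        v_gene=v_gene,
        chain=chain_of_v_gene(v_gene),
        cdr3_nt=junction_nt.upper(),
        junction_aa=junction_aa,
        cdr3_aa=extract_cdr3_imgt(junction_aa) if len(junction_aa) >= 3 else "",
        detection_count=detection_count,
        productive=productive,
    )


_REQUIRED_COLUMNS = ("v_call", "junction", "junction_aa", "duplicate_count")

_TRUE_STRINGS = {"t", "true", "1", "yes"}


def _parse_bool(value: object) -> bool | None:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return str(value).strip().lower() in _TRUE_STRINGS


def parse_airr(
    path,
    sample_id: str | None = None,
    lineage: Lineage | str = Lineage.other,
    genotype: str = "wild_type",
) -> RepertoireSample:
    """Read an AIRR Rearrangement TSV into a :class:`RepertoireSample`.

    Rows sharing a (normalized V gene, junction nucleotide) key are merged
    into one clone with ``detection_count`` equal to the summed
    ``duplicate_count``.  Rows lacking a junction are dropped and the count
    logged.

    Raises :class:`FormatError` on missing mandatory columns and
    :class:`EmptySampleError` when no clone survives parsing.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptySampleError(f"{path}: empty file") from None
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory AIRR column {col!r}")

    missing = df["junction"].isna() | (df["junction"].str.strip() == "")
    if missing.any():
        logger.info("%s: dropped %d rows lacking a junction", path, int(missing.sum()))
        df = df.loc[~missing]
    if df.empty:
        raise EmptySampleError(f"{path}: no rows with a junction")

    merged: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        v_gene = normalize_v_gene(row.v_call)
        nt = str(row.junction).upper()
        count = int(float(row.duplicate_count)) if pd.notna(row.duplicate_count) else 1
        key = (v_gene, nt)
        if key in merged:
            merged[key]["count"] += count
        else:
            merged[key] = {
                "v_call": row.v_call,
                "junction": nt,
                "junction_aa": str(row.junction_aa),
                "count": count,
                "productive": _parse_bool(getattr(row, "productive", None)),
            }

    clones = [
        make_clone(
            rec["v_call"],
            rec["junction"],
            rec["junction_aa"],
            detection_count=rec["count"],
            productive=rec["productive"],
        )
        for rec in merged.values()
    ]
    chains = {c.chain for c in clones}
    if isinstance(lineage, str):
        lineage = Lineage(lineage)
    return RepertoireSample(
        sample_id=sample_id or str(path),
        clones=clones,
        chain=chains.pop() if len(chains) == 1 else None,
        lineage=lineage,
        genotype=genotype,
    )


def write_airr(sample: RepertoireSample, path) -> None:
    """Write a sample as AIRR Rearrangement TSV (one row per clone)."""
    df = pd.DataFrame(
        {
            "sequence_id": [f"{sample.sample_id}-{i}" for i in range(len(sample))],
            "v_call": [c.v_gene for c in sample.clones],
            "junction": [c.cdr3_nt for c in sample.clones],
            "junction_aa": [c.junction_aa for c in sample.clones],
            "duplicate_count": [c.detection_count for c in sample.clones],
            "productive": ["T" if c.productive else "F" for c in sample.clones],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def filter_productive(sample: RepertoireSample) -> RepertoireSample:
    """Drop clones with an out-of-frame junction or a stop codon in it."""
    kept = [
        c
        for c in sample.clones
        if len(c.cdr3_nt) % 3 == 0 and "*" not in c.junction_aa
    ]
    return replace(sample, clones=kept)


def concat_clones(samples: Iterable[RepertoireSample]) -> list[CloneRecord]:
    """All clones across samples, duplicates preserved (no dedup)."""
    out: list[CloneRecord] = []
    for s in samples:
        out.extend(s.clones)
    return out
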
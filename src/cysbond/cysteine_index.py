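"""The cysteine index: fraction of clones with Cys near the CDR3 apex.

For a CDR3 of *n* amino acids the apex is the residue at the largest
position not greater than n/2 + 1 (1-based, CDR3-IMGT coordinates).  The
cysteine index of a sample is the percentage of clones carrying a Cys
within 2 positions of the apex.  Clones detected only once or twice in the
sample are excluded, as are beta-chain TRBV1 clones with CDR3 shorter than
8 amino acids: TRBV1 can carry a germline-encoded Cys at CDR3 position 2,
which falls inside the apex window only for CDR3s of length <= 7.  A sample
with no apex-Cys clone gets the reciprocal of its eligible clone count,
expressed as a percentage, so the index is always strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .repertoire_core import Chain, CloneRecord, EmptySampleError, RepertoireSample

#: Detection-count threshold: clones seen only once or twice are excluded.
DEFAULT_MIN_COUNT = 3
#: TRBV1 clones with CDR3-IMGT shorter than this are excluded (beta only).
DEFAULT_TRBV1_MIN_LENGTH = 8
#: Apex window half-width: "within 2 positions" is inclusive distance <= 2.
APEX_WINDOW = 2


@dataclass(frozen=True)
class CysIndexResult:
    """Cysteine index of one sample, with its exclusion bookkeeping."""

    sample_id: str
    chain: Chain | None
    n_eligible: int
    n_apex_cys: int
    index_percent: float
    zero_fallback_used: bool
    n_excluded_low_count: int
    n_excluded_trbv1: int

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "chain": self.chain.value if self.chain else None,
            "n_eligible": self.n_eligible,
            "n_apex_cys": self.n_apex_cys,
            "index_percent": self.index_percent,
            "zero_fallback_used": self.zero_fallback_used,
            "n_excluded_low_count": self.n_excluded_low_count,
            "n_excluded_trbv1": self.n_excluded_trbv1,
        }


def middle_position(n: int) -> int:
    """1-based apex position of an n-residue CDR3: floor(n/2) + 1."""
    if n < 1:
        raise ValueError(f"CDR3 length must be >= 1, got {n}")
    return n // 2 + 1


def has_apex_cysteine(cdr3_aa: str, window: int = APEX_WINDOW) -> bool:
    """True iff some Cys lies within ``window`` positions of the apex."""
    n = len(cdr3_aa)
    if n == 0:
        raise ValueError("empty CDR3")
    apex = middle_position(n)
    lo = max(1, apex - window)
    hi = min(n, apex + window)
    return "C" in cdr3_aa[lo - 1 : hi]


def eligible_clones(
    sample: RepertoireSample,
    min_count: int = DEFAULT_MIN_COUNT,
    trbv1_min_length: int = DEFAULT_TRBV1_MIN_LENGTH,
) -> tuple[list[CloneRecord], int, int]:
    """Clones entering the cysteine-index calculation, plus exclusion tallies.

    Returns ``(kept, n_excluded_low_count, n_excluded_trbv1)``.  The
    detection-count filter applies first; the TRBV1 short-CDR3 rule applies
    to beta-chain clones among those that pass it.
    """
    kept: list[CloneRecord] = []
    n_low = 0
    n_trbv1 = 0
    for clone in sample.clones:
        if clone.detection_count < min_count:
            n_low += 1
            continue
        if (
            clone.chain is Chain.beta
            and clone.v_gene.upper() == "TRBV1"
            and len(clone.cdr3_aa) < trbv1_min_length
        ):
            n_trbv1 += 1
            continue
        kept.append(clone)
    return kept, n_low, n_trbv1


def cysteine_index(
    sample: RepertoireSample,
    min_count: int = DEFAULT_MIN_COUNT,
    trbv1_min_length: int = DEFAULT_TRBV1_MIN_LENGTH,
) -> CysIndexResult:
    """Compute the cysteine index of one (productivity-filtered) sample.

    Each eligible clone counts once, regardless of detection count.  Raises
    :class:`EmptySampleError` when no clone is eligible — distinct from the
    zero-apex-Cys case, which uses the reciprocal fallback.
    """
    kept, n_low, n_trbv1 = eligible_clones(sample, min_count, trbv1_min_length)
    if not kept:
        raise EmptySampleError(
            f"{sample.sample_id}: no eligible clones for cysteine index"
        )
    n_cys = sum(1 for c in kept if has_apex_cysteine(c.cdr3_aa))
    if n_cys > 0:
        index = 100.0 * n_cys / len(kept)
        fallback = False
    else:
        index = 100.0 / len(kept)
        fallback = True
    return CysIndexResult(
        sample_id=sample.sample_id,
        chain=sample.chain,
        n_eligible=len(kept),
        n_apex_cys=n_cys,
        index_percent=index,
        zero_fallback_used=fallback,
        n_excluded_low_count=n_low,
        n_excluded_trbv1=n_trbv1,
    )
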
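"""isomiR detection and tailing/trimming profiling of small-RNA reads.

Reads are filtered (minimum length, dinucleotide-entropy low-complexity
filter), assigned to mature miRNAs by an exact anchored matcher against
each mature sequence in its precursor context (5' offsets of up to a few
nucleotides, a variable 3' end, at most ``max_mm`` substitutions in the
mature-overlapping portion, up to ``max_hits`` assignments per read), and
classified:

* ``canonical``  - exactly the mature sequence,
* ``trimmed``    - 3' end shortened,
* ``tailed``     - 3' nucleotides added; a tail is *templated* when it
  equals the precursor bases immediately downstream of the read's 3'
  genomic end, *non-templated* when no tail base matches, *mixed*
  otherwise,
* ``trimmed_tailed`` and ``five_prime_variant`` for the remaining shapes.

Multi-assigned reads keep their fewest-mismatch assignments with equal
fractional weight, so total weight equals the number of assigned reads.
Per-miRNA class counts are turned into proportions and library-size
normalized expression (count / library total x mean library total, then
log2(x + 1)).

This is a behavioral desk-scale reimplementation of a genome-alignment
workflow: templated/non-templated calls use the precursor's downstream
flank rather than a genome, and the genome-mismatch filter is replaced
by discarding reads that match a precursor region outside the mature
windows with fewer mismatches.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

ISOMIR_CLASSES = ("canonical", "trimmed", "tailed", "trimmed_tailed")


class ReferenceError_(ValueError):
    pass


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MatureReference:
    """A mature miRNA in its precursor context.

    ``mature_start`` is the 0-based offset of the mature sequence within
    the precursor; the precursor should extend >= 10 nt downstream of the
    mature 3' end so templated tails can be recognized.
    """

    mirna_id: str
    mature: str
    precursor: str
    mature_start: int

    def __post_init__(self):
        if _norm(self.precursor)[self.mature_start : self.mature_start + len(self.mature)] != _norm(
            self.mature
        ):
            raise ReferenceError_(
                f"mature {self.mirna_id} is not a substring of its precursor at offset "
                f"{self.mature_start}"
            )

    @property
    def downstream(self) -> str:
        return self.precursor[self.mature_start + len(self.mature) :]


def references_from_tables(
    matures: Mapping[str, str], precursors: pd.DataFrame
) -> List[MatureReference]:
    """Build :class:`MatureReference` objects from the generator's outputs
    (a mature dict plus a precursor table with ``mirna_id, sequence,
    mature_start``)."""
    idx = precursors.set_index("mirna_id")
    return [
        MatureReference(
            mirna_id=mid,
            mature=matures[mid],
            precursor=idx.loc[mid, "sequence"],
            mature_start=int(idx.loc[mid, "mature_start"]),
        )
        for mid in matures
    ]


# ---------------------------------------------------------------------------
# Read filtering
# ---------------------------------------------------------------------------

def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping-dinucleotide composition;
    0 for homopolymers and reads shorter than 2 nt."""
    s = _norm(seq)
    if len(s) < 2:
        return 0.0
    counts = Counter(s[i : i + 2] for i in range(len(s) - 1))
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def filter_reads(
    reads: Sequence[Tuple[str, str]],
    min_len: int = 14,
    entropy_cutoff: float = 0.5,
) -> Tuple[List[Tuple[str, str]], Dict[str, float]]:
    """Drop reads shorter than ``min_len`` nt or with dinucleotide entropy
    below ``entropy_cutoff`` bits.

    Returns the retained reads and a stats dict with the input/output
    counts and the fraction removed.
    """
    kept = [
        (rid, seq)
        for rid, seq in reads
        if len(seq) >= min_len and dinucleotide_entropy(seq) >= entropy_cutoff
    ]
    n_in = len(reads)
    return kept, {
        "n_in": float(n_in),
        "n_out": float(len(kept)),
        "fraction_removed": (n_in - len(kept)) / n_in if n_in else 0.0,
    }


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------

@dataclass
class IsomirCall:
    """One read-to-miRNA assignment with its isoform interpretation."""

    read_id: str
    mirna_id: str
    mismatches: int
    offset_5p: int  # read 5' start relative to the mature 5' end
    trim_3p: int  # nucleotides missing from the mature 3' end
    tail: str  # added 3' nucleotides (read alphabet)
    tail_type: str  # none / templated / non_templated / mixed
    isoform_class: str  # canonical / trimmed / tailed / trimmed_tailed / five_prime_variant
    weight: float = 1.0


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _best_alignment(
    read: str, ref: MatureReference, max_5p_shift: int, max_mm: int
) -> Optional[Tuple[int, int, int, str]]:
    """Best anchored, ungapped placement of ``read`` on ``ref``.

    Tries 5' offsets in [-max_5p_shift, +max_5p_shift] (relative to the
    mature 5' end, using precursor context for negative offsets and
    tails). Mismatches are counted on the mature-overlapping portion of
    the read only. Returns (mismatches, offset_5p, trim_3p, tail) of the
    best placement (fewest mismatches, then smallest |offset|, then least
    3' variation), or None.
    """
    prec = _norm(ref.precursor)
    mstart, mlen = ref.mature_start, len(ref.mature)
    best: Optional[Tuple[int, int, int, str]] = None
    best_key = None
    for off in range(-max_5p_shift, max_5p_shift + 1):
        gstart = mstart + off
        if gstart < 0:
            continue
        mature_end = mstart + mlen
        core_len = mature_end - gstart  # read bases that can overlap the mature
        if core_len <= 0:
            continue
        overlap = min(len(read), core_len)
        mm = _mismatches(read[:overlap], prec[gstart : gstart + overlap])
        if mm > max_mm:
            continue
        trim = core_len - len(read) if len(read) < core_len else 0
        tail = read[core_len:] if len(read) > core_len else ""
        key = (mm, abs(off), trim + len(tail))
        if best_key is None or key < best_key:
            best_key = key
            best = (mm, off, trim, tail)
    return best


def _genome_filter_hit(
    read: str, refs: Sequence[MatureReference], best_mm: int, max_5p_shift: int
) -> bool:
    """True when the read matches some precursor region *outside* the
    mature windows with fewer mismatches than its best mature placement
    (the desk-scale stand-in for the genome-mismatch filter)."""
    for ref in refs:
        prec = _norm(ref.precursor)
        lo = ref.mature_start - max_5p_shift
        hi = ref.mature_start + max_5p_shift
        for start in range(0, len(prec) - len(read) + 1):
            if lo <= start <= hi:
                continue
            if _mismatches(read, prec[start : start + len(read)]) < best_mm:
                return True
    return False


def assign_reads(
    reads: Sequence[Tuple[str, str]],
    refs: Sequence[MatureReference],
    max_mm: int = 2,
    max_hits: int = 100,
    max_5p_shift: int = 3,
    genome_filter: bool = True,
) -> List[IsomirCall]:
    """Assign reads to mature miRNAs and classify their isoforms.

    Multi-assigned reads keep the assignments with the fewest mismatches,
    split by equal fractional weight; reads with more than ``max_hits``
    acceptable placements are discarded, as are reads rescued with fewer
    mismatches by a non-mature precursor region (when ``genome_filter``).
    """
    if not refs:
        raise ReferenceError_("empty reference set")
    ids = [r.mirna_id for r in refs]
    if len(set(ids)) != len(ids):
        raise ReferenceError_("references must be non-redundant by id")
    calls: List[IsomirCall] = []
    for rid, raw in reads:
        read = _norm(raw)
        hits: List[Tuple[MatureReference, Tuple[int, int, int, str]]] = []
        for ref in refs:
            aln = _best_alignment(read, ref, max_5p_shift, max_mm)
            if aln is not None:
                hits.append((ref, aln))
        if not hits or len(hits) > max_hits:
            continue
        best_mm = min(a[0] for _, a in hits)
        # a perfect mature placement can never be beaten by an off-mature one
        if genome_filter and best_mm > 0 and _genome_filter_hit(read, refs, best_mm, max_5p_shift):
            continue
        kept = [(ref, a) for ref, a in hits if a[0] == best_mm]
        w = 1.0 / len(kept)
        for ref, (mm, off, trim, tail) in kept:
            call = IsomirCall(
                read_id=rid,
                mirna_id=ref.mirna_id,
                mismatches=mm,
                offset_5p=off,
                trim_3p=trim,
                tail=tail,
                tail_type="none",
                isoform_class="canonical",
                weight=w,
            )
            classify_isoform(call, ref)
            calls.append(call)
    return calls


def classify_isoform(call: IsomirCall, ref: MatureReference) -> IsomirCall:
    """Fill ``isoform_class`` and ``tail_type`` of a call in place.

    A 5' offset overrides the 3' classes and is reported separately as
    ``five_prime_variant``. Tail typing compares the tail with the
    precursor bases immediately downstream of the read's 3' genomic end.
    """
    if call.tail:
        down = _norm(ref.downstream)
        if len(down) < len(call.tail):
            raise ReferenceError_(
                f"precursor of {ref.mirna_id} lacks downstream context to type a "
                f"{len(call.tail)}-nt tail"
            )
        matches = sum(a == b for a, b in zip(call.tail, down))
        if matches == len(call.tail):
            call.tail_type = "templated"
        elif matches == 0:
            call.tail_type = "non_templated"
        else:
            call.tail_type = "mixed"
    else:
        call.tail_type = "none"
    if call.offset_5p != 0:
        call.isoform_class = "five_prime_variant"
    elif call.trim_3p and call.tail:
        call.isoform_class = "trimmed_tailed"
    elif call.trim_3p:
        call.isoform_class = "trimmed"
    elif call.tail:
        call.isoform_class = "tailed"
    else:
        call.isoform_class = "canonical"
    return call


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class IsomirProfile:
    """Per-miRNA weighted class counts and proportions for one library."""

    counts: pd.DataFrame  # index miRNA, columns isomiR classes (weighted counts)
    proportions: pd.DataFrame  # same shape; rows sum to 1
    five_prime_counts: pd.Series  # per-miRNA 5' variant weight (kept apart)

    @property
    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)


def build_profile(calls: Iterable[IsomirCall], include_five_prime: bool = False) -> IsomirProfile:
    """Aggregate calls into per-miRNA class counts and proportions.

    5'-variant reads are tallied separately and excluded from the
    trimming/tailing proportions unless ``include_five_prime`` (then they
    appear as their own class column).
    """
    rows = [
        (c.mirna_id, c.isoform_class, c.weight)
        for c in calls
    ]
    if not rows:
        raise ReferenceError_("no calls to profile")
    df = pd.DataFrame(rows, columns=["mirna_id", "isoform_class", "weight"])
    classes = list(ISOMIR_CLASSES) + (["five_prime_variant"] if include_five_prime else [])
    fp = (
        df[df["isoform_class"] == "five_prime_variant"]
        .groupby("mirna_id")["weight"]
        .sum()
    )
    if not include_five_prime:
        df = df[df["isoform_class"] != "five_prime_variant"]
    counts = (
        df.pivot_table(
            index="mirna_id", columns="isoform_class", values="weight", aggfunc="sum", fill_value=0.0
        )
        .reindex(columns=classes, fill_value=0.0)
    )
    counts.columns.name = None
    totals = counts.sum(axis=1)
    proportions = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    all_mirnas = counts.index
    fp = fp.reindex(all_mirnas, fill_value=0.0)
    return IsomirProfile(counts=counts, proportions=proportions, five_prime_counts=fp)


def normalize_libraries(counts: pd.DataFrame, library_totals: Mapping[str, float]) -> pd.DataFrame:
    """Library-size normalization: count / library_total x mean(totals),
    then log2(x + 1). ``counts`` columns are library ids."""
    totals = pd.Series(library_totals, dtype=float).reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ReferenceError_("every library needs a positive total")
    scaled = counts.div(totals, axis=1) * totals.mean()
    return np.log2(scaled + 1.0)


def compare_profiles(a: IsomirProfile, b: IsomirProfile) -> pd.DataFrame:
    """Per-miRNA, per-class proportion change from profile ``a`` to ``b``
    with a two-sided two-proportion z-test.

    Returns a long table with ``mirna_id, isoform_class, prop_a, prop_b,
    delta, p_value, increased`` (``delta`` = prop_b - prop_a; classes with
    more trimming/tailing in ``b`` have ``increased`` True).
    """
    if not a.counts.index.equals(b.counts.index) or list(a.counts.columns) != list(
        b.counts.columns
    ):
        raise ReferenceError_("profiles must share miRNA and class sets")
    rows = []
    for mid in a.counts.index:
        na, nb = a.counts.loc[mid].sum(), b.counts.loc[mid].sum()
        for cls in a.counts.columns:
            xa, xb = a.counts.loc[mid, cls], b.counts.loc[mid, cls]
            pa = xa / na if na else 0.0
            pb = xb / nb if nb else 0.0
            delta = pb - pa
            if na and nb:
                pooled = (xa + xb) / (na + nb)
                se = math.sqrt(pooled * (1 - pooled) * (1 / na + 1 / nb)) if 0 < pooled < 1 else 0.0
                z = delta / se if se else 0.0
                p = 2 * stats.norm.sf(abs(z)) if se else 1.0
            else:
                p = 1.0
            rows.append(
                {
                    "mirna_id": mid,
                    "isoform_class": cls,
                    "prop_a": pa,
                    "prop_b": pb,
                    "delta": delta,
                    "p_value": p,
                    "increased": delta > 0,
                }
            )
    return pd.DataFrame(rows)
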
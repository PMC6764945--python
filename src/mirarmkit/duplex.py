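"""miRNA:target duplex architecture.

A miRNA is aligned antiparallel against a candidate binding site with a
banded, affine-gap pairing model (Watson-Crick pair +2, G:U wobble +1,
mismatch 0, bulge open -2 / extend -1). The miRNA is aligned end to end;
unaligned target overhangs at either end of the site are free. This is a
score-based complementarity model, deliberately not a thermodynamic
(free-energy) one.

From the per-position pairing states a site is classified as

* ``extensive`` - near-complete complementarity with no central loop,
* ``tdmd_competent`` - perfect seed pairing (positions 2-7), extensive
  pairing of the 3'-adjacent region, a central loop/bulge opposite
  positions ~9-12, and at most two unpaired nucleotides at the miRNA
  3' extremity (the architecture that triggers target-directed miRNA
  degradation),
* ``seed_only`` - canonical seed match with little 3' support,
* ``none`` otherwise.

The module also scans transcripts for seed-anchored sites and designs
bulged sponge constructs (by default six sites separated by 4-nt
spacers) whose every site classifies as ``tdmd_competent``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

NEG_INF = float("-inf")

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class SequenceError(ValueError):
    pass


def _normalize_rna(seq: str, name: str) -> str:
    s = seq.upper().replace("T", "U")
    if not s or any(b not in "ACGU" for b in s):
        raise SequenceError(f"{name} contains characters outside the nucleotide alphabet: {seq!r}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet (T accepted on input)."""
    s = _normalize_rna(seq, "sequence")
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(s))


def _pair_state(mir_base: str, site_base: str) -> str:
    if (mir_base, site_base) in WC_PAIRS:
        return "WC"
    if (mir_base, site_base) in GU_PAIRS:
        return "GU"
    return "MM"


@dataclass(frozen=True)
class PairingScores:
    wc: float = 2.0
    gu: float = 1.0
    mismatch: float = 0.0
    gap_open: float = 2.0  # charged as a penalty
    gap_extend: float = 1.0

    def substitution(self, state: str) -> float:
        return {"WC": self.wc, "GU": self.gu, "MM": self.mismatch}[state]

    def gap(self, length: int) -> float:
        return self.gap_open + (length - 1) * self.gap_extend


@dataclass
class DuplexAlignment:
    """Pairing architecture of one miRNA:site duplex.

    ``states[i]`` describes miRNA position i+1 (1-based positions
    throughout): ``WC``, ``GU``, ``MM`` (aligned, unpaired) or
    ``MIR_BULGE`` (opposite a gap in the site). ``target_bulges`` lists
    internal runs of unaligned site bases as ``(after_pos, length)``,
    falling between miRNA positions ``after_pos`` and ``after_pos + 1``.
    ``site_start``/``site_end`` bound the aligned region on the site,
    0-based half-open (free overhangs excluded).
    """

    mirna: str
    site: str
    score: float
    states: List[str]
    target_bulges: List[Tuple[int, int]] = field(default_factory=list)
    site_start: int = 0
    site_end: int = 0
    central_window: Tuple[int, int] = (9, 12)

    def __len__(self) -> int:
        return len(self.mirna)

    def _paired(self, pos: int, seed_strict: bool = False) -> bool:
        st = self.states[pos - 1]
        return st == "WC" if seed_strict else st in ("WC", "GU")

    @property
    def seed_paired(self) -> int:
        """Watson-Crick paired positions within the seed (2-7)."""
        return sum(self.states[p - 1] == "WC" for p in range(2, 8))

    @property
    def three_prime_paired(self) -> int:
        """Paired (WC or GU) positions from 13 to the miRNA 3' end."""
        return sum(self._paired(p) for p in range(13, len(self) + 1))

    def supplementary_paired(self, last_offset: int = 3) -> int:
        """Paired positions in the 3'-adjacent region 13..L-``last_offset``
        (the miRNA's terminal nucleotides excluded)."""
        return sum(self._paired(p) for p in range(13, len(self) - last_offset + 1))

    @property
    def terminal_3p_mismatches(self) -> int:
        """Unpaired positions at the miRNA 3' extremity."""
        n = 0
        for p in range(len(self), 0, -1):
            if self._paired(p):
                break
            n += 1
        return n

    @property
    def central_unpaired(self) -> List[int]:
        lo, hi = self.central_window
        return [p for p in range(lo, hi + 1) if not self._paired(p)]

    @property
    def central_bulges(self) -> List[Tuple[int, int]]:
        lo, hi = self.central_window
        return [(p, k) for p, k in self.target_bulges if lo - 1 <= p <= hi - 1]

    @property
    def central_loop_present(self) -> bool:
        """An unpaired miRNA position within the central window, or a
        target bulge interrupting it."""
        return bool(self.central_unpaired) or bool(self.central_bulges)

    @property
    def loop_span(self) -> Optional[Tuple[int, int]]:
        pos = list(self.central_unpaired)
        pos += [p for p, _ in self.central_bulges] + [p + 1 for p, _ in self.central_bulges]
        if not pos:
            return None
        return (min(pos), max(pos))

    @property
    def paired_fraction(self) -> float:
        return sum(self._paired(p) for p in range(1, len(self) + 1)) / len(self)


def pair_duplex(
    mirna: str,
    site: str,
    band: int = 4,
    scores: PairingScores = PairingScores(),
) -> DuplexAlignment:
    """Banded affine-gap alignment of a miRNA against a target site.

    Both sequences are given 5'->3'; the duplex is antiparallel, so the
    site is reversed internally and miRNA position 1 pairs toward the
    site's 3' end. The miRNA is aligned globally; site overhangs beyond
    the miRNA's ends are free. The DP is restricted to a diagonal band of
    half-width ``band`` (widened by the length difference); ties resolve
    deterministically toward the leftmost optimum with fewest bulges.
    """
    m = _normalize_rna(mirna, "miRNA")
    s = _normalize_rna(site, "site")
    n, sm = len(m), len(s)
    if not (n - 4 <= sm <= n + 8):
        raise SequenceError(
            f"site length {sm} outside the supported window [{n - 4}, {n + 8}] for an "
            f"{n}-nt miRNA"
        )
    r = s[::-1]  # r[j-1] pairs miRNA position j when aligned on the diagonal

    lo = -band - max(0, n - sm)
    hi = band + max(0, sm - n)

    def in_band(i: int, j: int) -> bool:
        return lo <= j - i <= hi

    # Gotoh three-state DP. M: m[i] aligned to r[j]; X: m[i] opposite a gap
    # (miRNA bulge); Y: r[j] opposite a gap (target bulge).
    M = np.full((n + 1, sm + 1), NEG_INF)
    X = np.full((n + 1, sm + 1), NEG_INF)
    Y = np.full((n + 1, sm + 1), NEG_INF)
    Y[0, :] = 0.0  # leading site overhang is free
    for i in range(1, n + 1):
        if in_band(i, 0):
            X[i, 0] = -scores.gap(i)
        for j in range(1, sm + 1):
            if not in_band(i, j):
                continue
            st = _pair_state(m[i - 1], r[j - 1])
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            if best_prev > NEG_INF:
                M[i, j] = best_prev + scores.substitution(st)
            X[i, j] = max(
                M[i - 1, j] - scores.gap_open,
                X[i - 1, j] - scores.gap_extend,
                Y[i - 1, j] - scores.gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] - scores.gap_open,
                Y[i, j - 1] - scores.gap_extend,
                X[i, j - 1] - scores.gap_open,
            )

    # trailing site overhang free: end anywhere on row n in state M or X
    end_j, end_state, best = 0, "X", NEG_INF
    for j in range(0, sm + 1):
        for state, mat in (("M", M), ("X", X)):
            v = mat[n, j]
            if v > best + 1e-12:
                best, end_j, end_state = v, j, state
    if best == NEG_INF:
        raise SequenceError("no alignment within the band")

    # traceback
    states_rev: List[str] = []
    bulges_rev: List[Tuple[int, int]] = []
    i, j, state = n, end_j, end_state
    aligned_j: List[int] = []
    while i > 0:
        if state == "M":
            states_rev.append(_pair_state(m[i - 1], r[j - 1]))
            aligned_j.append(j)
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            for cand, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i - 1, j - 1] == prev:
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            states_rev.append("MIR_BULGE")
            v = X[i, j]
            if np.isclose(v, M[i - 1, j] - scores.gap_open):
                state = "M"
            elif np.isclose(v, X[i - 1, j] - scores.gap_extend):
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # Y: target bulge (or leading overhang when i == 0)
            run = 0
            while state == "Y" and j > 0 and i > 0:
                v = Y[i, j]
                run += 1
                if np.isclose(v, M[i, j - 1] - scores.gap_open):
                    state = "M"
                elif np.isclose(v, X[i, j - 1] - scores.gap_open):
                    state = "X"
                else:
                    state = "Y"
                j -= 1
                if state != "Y":
                    break
            if run:
                bulges_rev.append((i, run))
    states = states_rev[::-1]
    bulges = bulges_rev[::-1]
    # aligned region on r: [min_j, max_j]; plus internal bulged site bases
    if aligned_j:
        j_hi = max(aligned_j)
        j_lo_aln = min(aligned_j)
        # internal target bulges sit between aligned columns, already inside
        site_start = sm - j_hi
        site_end = sm - j_lo_aln + 1
    else:  # no aligned pair at all (degenerate): whole site is overhang
        site_start, site_end = 0, 0
    return DuplexAlignment(
        mirna=m,
        site=s,
        score=float(best),
        states=states,
        target_bulges=bulges,
        site_start=site_start,
        site_end=site_end,
    )


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteThresholds:
    """Classification thresholds.

    ``supp_min``: paired positions required in the 3'-adjacent region
    (13..L-3) for TDMD competence; ``extensive_frac``: fraction of all
    miRNA positions paired for an extensive site; ``max_terminal_mm``:
    tolerated unpaired nucleotides at the miRNA 3' extremity.
    """

    supp_min: int = 7
    extensive_frac: float = 0.9
    max_terminal_mm: int = 2


def classify_site(aln: DuplexAlignment, thresholds: SiteThresholds = SiteThresholds()) -> str:
    """Assign exactly one architecture label to an aligned site."""
    supp_window = max(0, len(aln) - 3 - 13 + 1)
    supp_needed = min(thresholds.supp_min, supp_window)
    supp = aln.supplementary_paired()
    seed_full = aln.seed_paired == 6
    if aln.paired_fraction >= thresholds.extensive_frac and not aln.central_loop_present:
        return "extensive"
    if (
        seed_full
        and aln.central_loop_present
        and supp >= supp_needed
        and aln.terminal_3p_mismatches <= thresholds.max_terminal_mm
    ):
        return "tdmd_competent"
    if seed_full and supp < supp_needed:
        return "seed_only"
    return "none"


# ---------------------------------------------------------------------------
# Transcript scanning
# ---------------------------------------------------------------------------

def scan_transcript(
    mirna: str,
    transcript: str,
    seed_span: Tuple[int, int] = (2, 7),
    thresholds: SiteThresholds = SiteThresholds(),
    band: int = 4,
    report_all: bool = False,
) -> pd.DataFrame:
    """Find and classify seed-anchored binding sites on one transcript.

    Every perfect match of the reverse complement of the miRNA seed
    (positions ``seed_span``, default 2-7) anchors a candidate window that
    is aligned with :func:`pair_duplex` and classified. Coordinates are
    0-based half-open on the given strand of the transcript; only the
    supplied strand is scanned. By default only sites with a label other
    than ``none`` are reported.
    """
    m = _normalize_rna(mirna, "miRNA")
    if not transcript:
        raise SequenceError("transcript is empty")
    tx = _normalize_rna(transcript, "transcript")
    L = len(m)
    a, b = seed_span
    seed_rc = revcomp(m[a - 1 : b])
    rows = []
    seen = set()
    start = tx.find(seed_rc)
    while start != -1:
        # the seed match covers the partners of positions b..a; the 3'
        # supplementary region pairs upstream, position 1 pairs downstream
        w0 = max(0, start - (L - b) - 8)
        w1 = min(len(tx), start + len(seed_rc) + (a - 1))
        window = tx[w0:w1]
        if len(window) >= L - 4:
            aln = pair_duplex(m, window, band=band)
            label = classify_site(aln, thresholds)
            s0, s1 = w0 + aln.site_start, w0 + aln.site_end
            key = (s0, s1, label)
            if key not in seen and (report_all or label != "none"):
                seen.add(key)
                rows.append(
                    {
                        "start": s0,
                        "end": s1,
                        "label": label,
                        "score": aln.score,
                        "seed_paired": aln.seed_paired,
                        "three_prime_paired": aln.three_prime_paired,
                        "loop_span": str(aln.loop_span) if aln.loop_span else "",
                        "seed_match_start": start,
                    }
                )
        start = tx.find(seed_rc, start + 1)
    return pd.DataFrame(
        rows,
        columns=[
            "start",
            "end",
            "label",
            "score",
            "seed_paired",
            "three_prime_paired",
            "loop_span",
            "seed_match_start",
        ],
    )


def scan_transcripts(
    mirnas: Dict[str, str], transcripts: Dict[str, str], **kwargs
) -> pd.DataFrame:
    """Scan every miRNA against every transcript; adds ``mirna_id`` and
    ``transcript_id`` columns."""
    frames = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            df = scan_transcript(mseq, tseq, **kwargs)
            if len(df):
                df.insert(0, "transcript_id", tid)
                df.insert(0, "mirna_id", mid)
                frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "mirna_id",
                "transcript_id",
                "start",
                "end",
                "label",
                "score",
                "seed_paired",
                "three_prime_paired",
                "loop_span",
                "seed_match_start",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Sponge design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpongeDesign:
    mirna_id: str
    mirna: str
    site: str
    construct: str
    site_coords: Tuple[Tuple[int, int], ...]  # 0-based half-open
    n_sites: int
    spacer: str


def design_sponge(
    mirna: str,
    mirna_id: str = "miRNA",
    n_sites: int = 6,
    spacer_len: int = 4,
    spacer_seq: Optional[str] = None,
    bulge_after: int = 10,
    bulge_len: int = 4,
) -> SpongeDesign:
    """Design a bulged sponge construct.

    One binding site is the reverse complement of the miRNA with a
    ``bulge_len``-nt insertion opposite the central region (between the
    partners of miRNA positions ``bulge_after`` and ``bulge_after``+1, by
    default within positions 9-12, so the duplex keeps a central bulge
    that prevents cleavage). ``n_sites`` copies are joined by
    ``spacer_len``-nt spacers; construct length is
    ``n_sites*(L+bulge_len) + (n_sites-1)*spacer_len``.
    """
    m = _normalize_rna(mirna, "miRNA")
    if not (18 <= len(m) <= 26):
        raise SequenceError("miRNA length must be 18-26 nt")
    if bulge_after <= 7:
        raise SequenceError("bulge position collides with the seed (positions 2-7)")
    if bulge_after > 11:
        raise SequenceError("bulge must interrupt the central 9-12 window")
    if n_sites < 1 or spacer_len < 0 or bulge_len < 1:
        raise SequenceError("invalid sponge geometry")
    rc = revcomp(m)
    cut = len(m) - bulge_after
    bulge = m[bulge_after - 1] * bulge_len  # copies a miRNA base: cannot pair
    site = rc[:cut] + bulge + rc[cut:]
    spacer = spacer_seq if spacer_seq is not None else "CACA"[:spacer_len].ljust(spacer_len, "C")
    spacer = _normalize_rna(spacer, "spacer") if spacer_len else ""
    if len(spacer) != spacer_len:
        raise SequenceError("spacer sequence length must equal spacer_len")
    construct = spacer.join([site] * n_sites)
    coords = []
    step = len(site) + spacer_len
    for k in range(n_sites):
        coords.append((k * step, k * step + len(site)))
    return SpongeDesign(
        mirna_id=mirna_id,
        mirna=m,
        site=site,
        construct=construct,
        site_coords=tuple(coords),
        n_sites=n_sites,
        spacer=spacer,
    )
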
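"""Synthetic-data generators with planted ground truth.

Every input the analysis modules consume can be simulated here: a paired
tumor/normal miRNA arm-pair cohort, qPCR Ct tables, biotin pull-down /
overexpression expression tables, reference sequences (mature miRNAs,
precursor hairpins with flanks, transcripts with planted binding sites),
small-RNA read sets with a known canonical/trimmed/tailed mixture, and
survival times driven by a linear risk score.

All randomness flows from a single integer seed through one
:class:`numpy.random.Generator` instance handed to each sub-generator;
there is no global random state, so identical configurations reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

RNA_BASES = "ACGU"

TREND_CLASSES = ("same_up", "same_down", "opposite_5p_up", "opposite_3p_up", "single", "null")
ISOFORM_CLASSES = ("canonical", "trimmed", "tailed_nt", "tailed_t")

#: Arm-pair trend composition emulating a large tumor/normal miRNA survey in
#: which ~35.9% of detectable arm pairs move coordinately (most of them down),
#: ~9.07% move in opposite directions, and the rest change in one arm only or
#: not at all.
DEFAULT_TREND_FRACTIONS: Dict[str, float] = {
    "same_up": 0.1091,
    "same_down": 0.25,
    "opposite_5p_up": 0.0457,
    "opposite_3p_up": 0.045,
    "single": 0.15,
    "null": 0.4002,
}

DEFAULT_ISOFORM_MIXTURE: Dict[str, float] = {
    "canonical": 0.70,
    "trimmed": 0.20,
    "tailed_nt": 0.05,
    "tailed_t": 0.05,
}


class ConfigError(ValueError):
    """Raised when a :class:`SimConfig` (or a generator argument) is invalid."""


def _check_proportions(name: str, props: Mapping[str, float], keys: Sequence[str]) -> None:
    if set(props) != set(keys):
        raise ConfigError(f"{name} must have exactly the keys {sorted(keys)}, got {sorted(props)}")
    vals = np.asarray(list(props.values()), dtype=float)
    if (vals < 0).any():
        raise ConfigError(f"{name} proportions must be non-negative")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{name} proportions must sum to 1 (got {vals.sum()!r})")


@dataclass(frozen=True)
class SimConfig:
    """All generator parameters, seeded.

    Parameters
    ----------
    seed:
        Integer seed; a fixed seed makes every generator deterministic.
    n_patients:
        Paired tumor/normal sample count for the cohort and qPCR generators.
    n_arm_pairs:
        Number of 5p/3p precursor arm pairs in the cohort.
    trend_fractions:
        Proportions of planted arm-pair trend classes
        (``same_up``/``same_down``/``opposite_5p_up``/``opposite_3p_up``/
        ``single``/``null``); must sum to 1.
    lognormal_sd:
        Biological patient-to-patient dispersion of expression, as the
        standard deviation of multiplicative (log-scale) noise.
    fold_effect:
        Multiplicative tumor/normal effect applied to dysregulated arms.
    n_genes, n_enriched:
        Gene universe and spiked-gene count for the pull-down generator.
    er_effect:
        True enrichment ratio of spiked genes in the bait pull-down.
    depletion_log2fc:
        Mean log2 fold change of true targets in the overexpression library.
    tech_sd:
        Technical (library-to-library) multiplicative noise for sequencing
        abundance tables, on the log scale. Separate from ``lognormal_sd``
        because the pull-down design splits one lysate across libraries.
    isoform_mixture:
        Proportions of ``canonical``/``trimmed``/``tailed_nt``/``tailed_t``
        small-RNA reads; must sum to 1.
    n_reads:
        Number of small-RNA reads to draw.
    read_error_rate:
        Per-base substitution probability applied to finished reads.
    hazard_beta:
        Log-hazard per unit of risk score in the survival generator.
    censor_rate:
        Proportion of subjects independently censored.
    library_sizes:
        Total counts of the simulated small-RNA libraries.
    """

    seed: int = 0
    n_patients: int = 50
    n_arm_pairs: int = 800
    trend_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREND_FRACTIONS)
    )
    lognormal_sd: float = 0.3
    fold_effect: float = 4.0
    n_genes: int = 5000
    n_enriched: int = 200
    er_effect: float = 3.0
    depletion_log2fc: float = -1.0
    tech_sd: float = 0.03
    isoform_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOFORM_MIXTURE)
    )
    n_reads: int = 10000
    read_error_rate: float = 0.0
    hazard_beta: float = 1.0
    censor_rate: float = 0.2
    library_sizes: Tuple[int, ...] = (1_000_000,)

    def __post_init__(self) -> None:
        _check_proportions("trend_fractions", self.trend_fractions, TREND_CLASSES)
        _check_proportions("isoform_mixture", self.isoform_mixture, ISOFORM_CLASSES)
        for name in ("n_patients", "n_arm_pairs", "n_genes", "n_reads"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_enriched < 0 or self.n_enriched >= self.n_genes:
            raise ConfigError("n_enriched must satisfy 0 <= n_enriched < n_genes")
        if self.lognormal_sd < 0 or self.tech_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.er_effect <= 0 or self.fold_effect <= 0:
            raise ConfigError("fold_effect and er_effect must be > 0")
        if not (0.0 <= self.read_error_rate < 1.0):
            raise ConfigError("read_error_rate must be in [0, 1)")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ConfigError("censor_rate must be in [0, 1]")
        if not np.isfinite(self.hazard_beta):
            raise ConfigError("hazard_beta must be finite")
        if any(t <= 0 for t in self.library_sizes):
            raise ConfigError("library_sizes must be positive")

    def rng(self) -> np.random.Generator:
        """A fresh generator seeded from this configuration."""
        return np.random.default_rng(self.seed)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted truth labels for recovery tests.

    Only the fields relevant to the generator that produced the object are
    populated; each generated entity appears exactly once.
    """

    trend_labels: Optional[Dict[str, str]] = None
    enriched_gene_ids: Optional[Set[str]] = None
    true_target_ids: Optional[Set[str]] = None
    isoform_labels: Optional[Dict[str, Tuple[str, str]]] = None  # read id -> (mirna, class)
    risk_scores: Optional[Dict[str, float]] = None
    site_classes: Optional[pd.DataFrame] = None  # transcript, mirna, start, end, label


# ---------------------------------------------------------------------------
# Cohort of paired arm-pair expression
# ---------------------------------------------------------------------------

def gen_cohort(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Simulate a paired tumor/normal cohort of 5p/3p arm pairs.

    Each arm pair gets a lognormal baseline; tumor values of dysregulated
    arms are multiplied (up) or divided (down) by ``fold_effect``; all
    values carry multiplicative noise of scale ``lognormal_sd``.

    Returns a tidy table with columns ``pair_id, arm, patient_id, normal,
    tumor`` and a :class:`GroundTruth` with one trend label per pair.
    """
    rng = config.rng() if rng is None else rng
    classes = list(TREND_CLASSES)
    probs = np.array([config.trend_fractions[c] for c in classes])
    labels = rng.choice(classes, size=config.n_arm_pairs, p=probs)

    n_pat, sd, fold = config.n_patients, config.lognormal_sd, config.fold_effect
    rows: List[pd.DataFrame] = []
    truth: Dict[str, str] = {}
    patients = [f"P{i:03d}" for i in range(n_pat)]
    for k, label in enumerate(labels):
        pair_id = f"pair{k:04d}"
        truth[pair_id] = label
        # tumor fold per arm
        if label == "same_up":
            f5, f3 = fold, fold
        elif label == "same_down":
            f5, f3 = 1 / fold, 1 / fold
        elif label == "opposite_5p_up":
            f5, f3 = fold, 1 / fold
        elif label == "opposite_3p_up":
            f5, f3 = 1 / fold, fold
        elif label == "single":
            # one arm moves (either direction), the other stays
            moved = fold if rng.random() < 0.5 else 1 / fold
            if rng.random() < 0.5:
                f5, f3 = moved, 1.0
            else:
                f5, f3 = 1.0, moved
        else:  # null
            f5, f3 = 1.0, 1.0
        for arm, f in (("5p", f5), ("3p", f3)):
            base = rng.lognormal(mean=3.0, sigma=1.0)
            normal = base * np.exp(rng.normal(0.0, sd, n_pat))
            tumor = base * f * np.exp(rng.normal(0.0, sd, n_pat))
            rows.append(
                pd.DataFrame(
                    {
                        "pair_id": pair_id,
                        "arm": arm,
                        "patient_id": patients,
                        "normal": normal,
                        "tumor": tumor,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    return table, GroundTruth(trend_labels=truth)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_qpcr(
    config: SimConfig,
    true_ratios: Mapping[str, float],
    n_replicates: int = 3,
    replicate_sd: float = 0.2,
    baseline_ct: float = 30.0,
    reference_gene: str = "U6",
    case_condition: str = "tumor",
    calibrator_condition: str = "normal",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate a Ct table for relative quantification.

    Ct = baseline − log2(abundance) + N(0, replicate_sd); the reference
    gene has constant abundance in both conditions, target genes carry the
    requested case/calibrator abundance fold.

    Returns a long table with columns ``sample, gene, condition, replicate,
    ct``; one synthetic sample per patient.
    """
    rng = config.rng() if rng is None else rng
    for g, f in true_ratios.items():
        if not (f > 0):
            raise ConfigError(f"fold for {g!r} must be > 0, got {f!r}")
    if n_replicates <= 0:
        raise ConfigError("n_replicates must be > 0")

    recs = []
    samples = [f"S{i:03d}" for i in range(config.n_patients)]
    genes = {reference_gene: 1.0, **dict(true_ratios)}
    for sample in samples:
        for gene, fold in genes.items():
            for condition in (calibrator_condition, case_condition):
                abundance = 1.0
                if gene != reference_gene and condition == case_condition:
                    abundance = fold
                ct0 = baseline_ct - np.log2(abundance)
                noise = rng.normal(0.0, replicate_sd, n_replicates) if replicate_sd > 0 else np.zeros(n_replicates)
                for r in range(n_replicates):
                    recs.append((sample, gene, condition, r, ct0 + noise[r]))
    return pd.DataFrame(recs, columns=["sample", "gene", "condition", "replicate", "ct"])


# ---------------------------------------------------------------------------
# Pull-down libraries
# ---------------------------------------------------------------------------

def gen_pulldown(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Simulate bait/control pull-down and input libraries plus an
    overexpression experiment with spiked true targets.

    Returns a genes x libraries abundance table with columns ``bait_pd,
    ctrl_pd, bait_input, ctrl_input, oe, oe_ctrl`` (FPKM-like units) and a
    :class:`GroundTruth` carrying the spiked/enriched gene ids (which are
    also the true targets depleted upon overexpression).
    """
    rng = config.rng() if rng is None else rng
    n, k = config.n_genes, config.n_enriched
    genes = np.array([f"G{i:05d}" for i in range(n)])
    spiked = rng.choice(n, size=k, replace=False)
    is_spiked = np.zeros(n, dtype=bool)
    is_spiked[spiked] = True

    base = rng.lognormal(mean=3.0, sigma=1.0, size=n)  # median ~20 FPKM

    def lib(expected: np.ndarray) -> np.ndarray:
        return expected * np.exp(rng.normal(0.0, config.tech_sd, n))

    bait_pd_expected = base * np.where(is_spiked, config.er_effect, 1.0)
    oe_expected = base * np.where(is_spiked, 2.0 ** config.depletion_log2fc, 1.0)

    table = pd.DataFrame(
        {
            "bait_pd": lib(bait_pd_expected),
            "ctrl_pd": lib(base),
            "bait_input": lib(base),
            "ctrl_input": lib(base),
            "oe": lib(oe_expected),
            "oe_ctrl": lib(base),
        },
        index=pd.Index(genes, name="gene"),
    )
    enriched = set(genes[is_spiked])
    return table, GroundTruth(enriched_gene_ids=enriched, true_target_ids=set(enriched))


# ---------------------------------------------------------------------------
# Reference sequences with planted binding sites
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp_rna(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=length))


def _non_pairing_base(b: str) -> str:
    """A target base that can neither Watson–Crick nor wobble pair with b."""
    return {"A": "C", "C": "A", "G": "A", "U": "C"}[b]


def _background(rng: np.random.Generator, length: int, forbidden: Sequence[str]) -> str:
    """Random RNA avoiding every k-mer in ``forbidden`` (seed complements)."""
    for _ in range(200):
        s = _random_rna(rng, length)
        if not any(f in s for f in forbidden):
            return s
    raise RuntimeError("could not sample background avoiding seed matches")


def make_site(
    mirna: str,
    site_class: str,
    rng: Optional[np.random.Generator] = None,
    bulge_after: int = 10,
    bulge_len: int = 4,
    terminal_mismatches: int = 2,
) -> str:
    """Construct a binding-site sequence of a requested architecture class.

    ``extensive`` is the full reverse complement; ``tdmd_competent`` adds a
    central target bulge opposite the miRNA 9-12 region (and optionally
    mutates the partners of the miRNA's terminal 3' nucleotides);
    ``seed_only`` pairs positions 1-8 only, with a non-pairing 3' region.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    L = len(mirna)
    rc = _revcomp_rna(mirna)  # rc[k] pairs miRNA position L-k (1-based)
    if site_class == "extensive":
        return rc
    if site_class == "tdmd_competent":
        # target bulge between the partners of miRNA positions bulge_after
        # and bulge_after+1; bulge bases copy a central miRNA base so they
        # cannot pair.
        cut = L - bulge_after
        bulge = mirna[bulge_after - 1] * bulge_len
        site = rc[:cut] + bulge + rc[cut:]
        if terminal_mismatches:
            # partners of miRNA positions L, L-1, ... sit at the site 5' end
            site = (
                "".join(_non_pairing_base(mirna[L - 1 - i]) for i in range(terminal_mismatches))
                + site[terminal_mismatches:]
            )
        return site
    if site_class == "seed_only":
        # pair positions 1..8, everything 3' of position 8 unpairable
        paired = rc[L - 8 :]  # partners of positions 8..1
        rest = "".join(_non_pairing_base(b) for b in reversed(mirna[8:]))
        return rest + paired
    raise ConfigError(f"unknown site class {site_class!r}")


def gen_references(
    config: SimConfig,
    n_mirnas: int = 4,
    mirna_len: int = 22,
    flank_len: int = 25,
    transcript_len: int = 200,
    site_classes: Sequence[str] = ("seed_only", "tdmd_competent", "extensive", "none"),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, str], pd.DataFrame, Dict[str, str], GroundTruth]:
    """Generate mature miRNAs, precursor hairpins with flanks, and
    transcripts embedding binding sites of known class.

    Returns ``(matures, precursor_table, transcripts, truth)`` where
    ``precursor_table`` has columns ``mirna_id, precursor_id, sequence,
    mature_start`` (mature is a substring of the precursor at that offset)
    and ``truth.site_classes`` records every planted site, 0-based
    half-open on its transcript.
    """
    rng = config.rng() if rng is None else rng
    matures: Dict[str, str] = {}
    prec_rows = []
    for i in range(n_mirnas):
        mid = f"miR-{900 + i}-5p"
        mature = _random_rna(rng, mirna_len)
        up = _random_rna(rng, flank_len)
        down = _random_rna(rng, flank_len)
        matures[mid] = mature
        prec_rows.append((mid, f"pre-miR-{900 + i}", up + mature + down, flank_len))
    precursors = pd.DataFrame(
        prec_rows, columns=["mirna_id", "precursor_id", "sequence", "mature_start"]
    )

    seeds = [_revcomp_rna(m[1:7]) for m in matures.values()]
    transcripts: Dict[str, str] = {}
    site_rows = []
    for mid, mature in matures.items():
        for cls in site_classes:
            tid = f"tx_{mid}_{cls}"
            bg = _background(rng, transcript_len, seeds)
            if cls == "none":
                transcripts[tid] = bg
                continue
            # planted TDMD sites keep full terminal pairing so their
            # coordinates are alignment-unambiguous; terminal-mismatch
            # variants are available through make_site directly
            site = make_site(mature, cls, rng, terminal_mismatches=0)
            pos = int(rng.integers(20, transcript_len - len(site) - 20))
            transcripts[tid] = bg[:pos] + site + bg[pos + len(site) :]
            site_rows.append((tid, mid, pos, pos + len(site), cls))
    truth = GroundTruth(
        site_classes=pd.DataFrame(
            site_rows, columns=["transcript_id", "mirna_id", "start", "end", "label"]
        )
    )
    return matures, precursors, transcripts, truth


# ---------------------------------------------------------------------------
# Small-RNA reads
# ---------------------------------------------------------------------------

def gen_small_rna_reads(
    config: SimConfig,
    precursors: pd.DataFrame,
    matures: Mapping[str, str],
    rng: Optional[np.random.Generator] = None,
    max_trim: int = 3,
    max_tail: int = 3,
) -> Tuple[List[Tuple[str, str]], GroundTruth]:
    """Sample small-RNA reads from the configured isoform mixture.

    canonical = the mature sequence; trimmed = mature minus 1..``max_trim``
    3' nucleotides; tailed_t = mature plus 1..``max_tail`` nucleotides
    copied from the precursor immediately downstream (templated);
    tailed_nt = mature plus nucleotides each drawn from the 3 bases that
    differ from the precursor's downstream base (non-templated by
    construction). Substitution errors are applied at ``read_error_rate``.

    Returns ``[(read_id, sequence), ...]`` (RNA alphabet) and a
    :class:`GroundTruth` mapping read id -> (mirna_id, class label).
    """
    rng = config.rng() if rng is None else rng
    classes = list(ISOFORM_CLASSES)
    probs = np.array([config.isoform_mixture[c] for c in classes])
    prec = precursors.set_index("mirna_id")
    mids = list(matures)
    for mid in mids:
        mature = matures[mid]
        if len(mature) <= max_trim:
            raise ConfigError(f"mature {mid} shorter than max trim {max_trim}")
        row = prec.loc[mid]
        down = row["sequence"][row["mature_start"] + len(mature) :]
        if len(down) < max_tail:
            raise ConfigError(f"precursor of {mid} lacks a {max_tail}-nt downstream flank")

    which_mir = rng.integers(0, len(mids), size=config.n_reads)
    which_cls = rng.choice(classes, size=config.n_reads, p=probs)
    reads: List[Tuple[str, str]] = []
    labels: Dict[str, Tuple[str, str]] = {}
    bases = np.array(list(RNA_BASES))
    for i in range(config.n_reads):
        mid = mids[which_mir[i]]
        cls = which_cls[i]
        mature = matures[mid]
        row = prec.loc[mid]
        downstream = row["sequence"][row["mature_start"] + len(mature) :]
        if cls == "canonical":
            seq = mature
        elif cls == "trimmed":
            seq = mature[: len(mature) - int(rng.integers(1, max_trim + 1))]
        elif cls == "tailed_t":
            k = int(rng.integers(1, max_tail + 1))
            seq = mature + downstream[:k]
        else:  # tailed_nt
            k = int(rng.integers(1, max_tail + 1))
            tail = "".join(
                rng.choice([b for b in RNA_BASES if b != downstream[j]]) for j in range(k)
            )
            seq = mature + tail
        if config.read_error_rate > 0:
            arr = np.array(list(seq))
            hits = rng.random(len(arr)) < config.read_error_rate
            for j in np.flatnonzero(hits):
                arr[j] = rng.choice(bases[bases != arr[j]])
            seq = "".join(arr)
        rid = f"read{i:06d}"
        reads.append((rid, seq))
        labels[rid] = (mid, cls)
    return reads, GroundTruth(isoform_labels=labels)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def gen_survival(
    config: SimConfig,
    risk_scores: Mapping[str, float],
    baseline_hazard: float = np.log(2) / 1000.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Exponential survival times with hazard h0 * exp(beta * score).

    Each subject is independently censored with probability ``censor_rate``
    (censoring time uniform on [0, event time]). Returns a table with
    columns ``patient_id, time, event`` (time in days, event True =
    death observed).
    """
    rng = config.rng() if rng is None else rng
    ids = list(risk_scores)
    scores = np.array([risk_scores[p] for p in ids], dtype=float)
    rates = baseline_hazard * np.exp(config.hazard_beta * scores)
    times = rng.exponential(1.0 / rates)
    censored = rng.random(len(ids)) < config.censor_rate
    obs = np.where(censored, rng.uniform(0.0, times), times)
    df = pd.DataFrame({"patient_id": ids, "time": obs, "event": ~censored})
    return df, GroundTruth(risk_scores=dict(zip(ids, scores)))
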
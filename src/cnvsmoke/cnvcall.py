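"""CNV calling from probe intensities and polymorphic component construction.

Three calling-side primitives:

* :func:`viterbi_segment` — a deliberately simple 4-state hidden Markov model
  (CN0, CN1, CN2, CN3) over probes, with Gaussian LRR emissions and a
  BAF-consistency term (heterozygous BAF mass argues against deletion
  states).  Maximal runs of non-diploid states become calls.
* :func:`genotype_median_lrr` — the replication-style genotyper: per-subject
  median LRR over a region, fit by a 1-D Gaussian mixture whose components
  are mapped onto copy numbers by proximity to the canonical emission means.
* :func:`build_components` — population-level polymorphic components from
  per-subject calls by breakpoint union: atomic intervals between
  consecutive breakpoints, per-subject copy numbers from covering calls,
  adjacent intervals with identical copy-number profiles merged, retained
  when carrier frequency strictly exceeds a threshold (default 1%).

Coordinates are 1-based inclusive; a span is reported as end - start
(matching the arithmetic convention of SNP-array CNV reports, where the
1,691 bp deletion runs from 6212573 to 6214264).  BED export converts to
0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from cnvsmoke.simdata import CANONICAL_LRR_MEANS, ProbePanel

logger = logging.getLogger(__name__)

__all__ = [
    "CNVCall", "CNVComponent", "HMMParams",
    "viterbi_segment", "genotype_median_lrr", "build_components", "span_bp",
    "parse_rawcnv", "write_rawcnv",
]

STATES = (0, 1, 2, 3)        # copy numbers modelled by the HMM
DIPLOID = 2

# BAF cluster centers and weights per copy-number state at B-allele
# population frequency 0.5 (binomial genotype weights); CN0 has no signal.
_BAF_CLUSTERS = {
    1: (np.array([0.0, 1.0]), np.array([0.5, 0.5])),
    2: (np.array([0.0, 0.5, 1.0]), np.array([0.25, 0.5, 0.25])),
    3: (np.array([0.0, 1 / 3, 2 / 3, 1.0]), np.array([0.125, 0.375, 0.375, 0.125])),
}


@dataclass(frozen=True)
class CNVCall:
    """One non-diploid segment called for one subject."""

    subject_id: str
    chrom: str
    start_bp: int
    end_bp: int
    copy_number: int
    n_probes: int
    confidence: float = float("nan")

    def __post_init__(self) -> None:
        if self.copy_number == DIPLOID:
            raise ValueError("a CNV call is by definition non-diploid")
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError(f"unsupported copy number {self.copy_number}")
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"end {self.end_bp} < start {self.start_bp} for {self.subject_id}")
        if self.n_probes < 1:
            raise ValueError("a call must span at least one probe")

    @property
    def span(self) -> int:
        return span_bp(self.start_bp, self.end_bp)


@dataclass
class CNVComponent:
    """A population-level CNV component with per-subject copy numbers."""

    chrom: str
    start_bp: int
    end_bp: int
    copy_number_by_subject: np.ndarray    # int array, one entry per subject
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.copy_number_by_subject = np.asarray(
            self.copy_number_by_subject, dtype=np.int16)

    @property
    def carrier_count(self) -> int:
        return int(np.sum(self.copy_number_by_subject != DIPLOID))

    @property
    def frequency(self) -> float:
        return self.carrier_count / self.copy_number_by_subject.size

    @property
    def component_id(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"

    @property
    def deleted_copies(self) -> np.ndarray:
        return np.clip(DIPLOID - self.copy_number_by_subject, 0, None)


@dataclass
class HMMParams:
    """Emission and transition parameters of the 4-state segmentation HMM."""

    lrr_means: dict[int, float] = field(
        default_factory=lambda: dict(CANONICAL_LRR_MEANS))
    lrr_sd: float = 0.2
    baf_sd: float = 0.05
    baf_weight: float = 1.0      # scale of the BAF-consistency term
    stay_prob: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.stay_prob < 1.0):
            raise ValueError(f"stay_prob must be in (0,1), got {self.stay_prob}")
        if self.lrr_sd <= 0 or self.baf_sd <= 0:
            raise ValueError("emission SDs must be positive")


def span_bp(start_bp: int, end_bp: int) -> int:
    """Span of a segment as end - start (1-based inclusive endpoints)."""
    if end_bp < start_bp:
        raise ValueError(f"end_bp {end_bp} < start_bp {start_bp}")
    return int(end_bp) - int(start_bp)


# ---------------------------------------------------------------------------
# HMM segmentation


def _baf_loglik(baf: np.ndarray, state: int, sd: float) -> np.ndarray:
    """Log-density of BAF values under one copy-number state.

    CN0 probes carry no allelic signal: BAF is uniform on [0,1], log-density
    0.  Other states are equal-variance Gaussian mixtures around their
    genotype cluster centers.
    """
    if state == 0:
        return np.zeros_like(baf)
    centers, weights = _BAF_CLUSTERS[state]
    dens = np.zeros_like(baf)
    for c, w in zip(centers, weights):
        dens += w * norm.pdf(baf, loc=c, scale=sd)
    return np.log(np.maximum(dens, 1e-300))


def emission_loglik(panel: ProbePanel, hmm: HMMParams) -> np.ndarray:
    """Per-state emission log-likelihoods, shape (subjects, probes, 4).

    Probes with non-finite LRR or BAF are uninformative: their emission
    contribution is zero for every state (they are skipped and logged).
    """
    bad = ~(np.isfinite(panel.lrr) & np.isfinite(panel.baf))
    if bad.any():
        logger.warning("skipping %d non-finite probe intensities", int(bad.sum()))
    lrr = np.where(bad, 0.0, panel.lrr)
    baf = np.where(bad, 0.5, panel.baf)
    out = np.empty(panel.lrr.shape + (len(STATES),))
    for s in STATES:
        ll = norm.logpdf(lrr, loc=hmm.lrr_means[s], scale=hmm.lrr_sd)
        ll = ll + hmm.baf_weight * _baf_loglik(baf, s, hmm.baf_sd)
        out[:, :, s] = ll
    out[bad, :] = 0.0
    return out


def _log_transition(hmm: HMMParams) -> np.ndarray:
    t = np.full((4, 4), np.log((1.0 - hmm.stay_prob) / 3.0))
    np.fill_diagonal(t, np.log(hmm.stay_prob))
    return t


def _log_initial(hmm: HMMParams) -> np.ndarray:
    """Initial state distribution: as if preceded by a diploid probe."""
    pi = np.full(4, (1.0 - hmm.stay_prob) / 3.0)
    pi[DIPLOID] = hmm.stay_prob
    return np.log(pi)


def viterbi_path(emis: np.ndarray, hmm: HMMParams) -> np.ndarray:
    """Maximum-probability state path for one subject (emis: probes x 4)."""
    n_probes = emis.shape[0]
    log_t = _log_transition(hmm)
    score = _log_initial(hmm) + emis[0]
    back = np.zeros((n_probes, 4), dtype=np.int8)
    for p in range(1, n_probes):
        cand = score[:, None] + log_t            # prev x next
        back[p] = np.argmax(cand, axis=0)
        score = cand[back[p], np.arange(4)] + emis[p]
    path = np.empty(n_probes, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for p in range(n_probes - 1, 0, -1):
        path[p - 1] = back[p, path[p]]
    return path


def viterbi_segment(panel: ProbePanel, hmm: HMMParams | None = None) -> list[CNVCall]:
    """Segment every subject's probe intensities into CNV calls.

    Per subject, the Viterbi path over the 4 copy-number states is computed
    under Gaussian LRR emissions plus the BAF-consistency term; each maximal
    run of a common non-diploid state becomes a call with probe-anchored
    boundaries.  Confidence is the emission log-likelihood of the called
    state minus the all-diploid alternative over the call's probes (the
    within-run transition terms cancel).
    """
    if hmm is None:
        hmm = HMMParams()
    if panel.n_probes == 0 or panel.n_subjects == 0:
        return []
    emis = emission_loglik(panel, hmm)
    calls: list[CNVCall] = []
    for i in range(panel.n_subjects):
        path = viterbi_path(emis[i], hmm)
        p = 0
        while p < panel.n_probes:
            state = path[p]
            q = p
            while q + 1 < panel.n_probes and path[q + 1] == state:
                q += 1
            if state != DIPLOID:
                conf = float(np.sum(emis[i, p:q + 1, state]
                                    - emis[i, p:q + 1, DIPLOID]))
                calls.append(CNVCall(
                    subject_id=panel.subject_ids[i], chrom=panel.chrom,
                    start_bp=int(panel.positions[p]),
                    end_bp=int(panel.positions[q]),
                    copy_number=int(state), n_probes=q - p + 1,
                    confidence=conf))
            p = q + 1
    return calls


# ---------------------------------------------------------------------------
# Median-LRR mixture genotyping


def genotype_median_lrr(panel: ProbePanel, region: tuple[str, int, int],
                        max_components: int = 4, random_state: int = 0,
                        ) -> tuple[np.ndarray, dict]:
    """Copy-number genotypes from a Gaussian mixture on per-subject median LRR.

    Per subject, the median LRR over in-region probes is computed; a 1-D
    Gaussian mixture with up to ``max_components`` components (selected by
    BIC) is fit; fitted components are mapped onto copy numbers by proximity
    to the canonical emission means and hard assignments returned.  If the
    fit is degenerate or a fitted mean cannot be identified with a canonical
    state, the genotyper falls back to nearest-canonical-mean classification
    with a warning.

    Returns ``(copy_numbers, summary)`` where summary records the method,
    the number of mixture components and the fitted means/weights.
    """
    chrom, start, end = region
    mask = (panel.positions >= start) & (panel.positions <= end)
    if chrom != panel.chrom:
        mask = np.zeros_like(mask)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"region {chrom}:{start}-{end} overlaps only {int(mask.sum())} "
            "probes; need at least 3")
    med = np.median(panel.lrr[:, mask], axis=1)
    canon = np.array([CANONICAL_LRR_MEANS[s] for s in STATES])

    def _fallback(reason: str):
        logger.warning("mixture fit degenerate (%s); falling back to "
                       "fixed-means classification", reason)
        cn = np.array(STATES)[np.argmin(np.abs(med[:, None] - canon[None, :]),
                                        axis=1)]
        return cn.astype(np.int16), {
            "method": "fixed_means", "n_components": None,
            "means": canon.tolist(), "weights": None}

    x = med[:, None]
    if np.ptp(med) < 1e-12:
        # single point mass: the mixture is unidentifiable
        return _fallback("zero spread")
    best = None
    for k in range(1, min(max_components, len(np.unique(med))) + 1):
        try:
            gm = GaussianMixture(n_components=k, n_init=3,
                                 random_state=random_state,
                                 covariance_type="full",
                                 reg_covar=1e-6).fit(x)
        except ValueError:
            continue
        bic = gm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, gm)
    if best is None:
        return _fallback("no converged fit")
    gm = best[1]
    means = gm.means_.ravel()
    state_of = np.array(STATES)[np.argmin(np.abs(means[:, None] - canon[None, :]),
                                          axis=1)]
    if len(set(state_of.tolist())) != means.size or \
            np.any(np.min(np.abs(means[:, None] - canon[None, :]), axis=1) > 0.5):
        return _fallback("fitted means not identifiable with canonical states")
    comp = gm.predict(x)
    cn = state_of[comp].astype(np.int16)
    summary = {"method": "gaussian_mixture", "n_components": int(means.size),
               "means": means.tolist(), "weights": gm.weights_.ravel().tolist()}
    return cn, summary


# ---------------------------------------------------------------------------
# Polymorphic component construction


def build_components(calls: list[CNVCall], cohort_size: int,
                     min_frequency: float = 0.01,
                     subject_ids: list[str] | None = None,
                     ) -> list[CNVComponent]:
    """Population-level polymorphic components from per-subject calls.

    Breakpoints per chromosome are the union of call boundaries; atomic
    intervals between consecutive breakpoints get each subject's copy
    number from any covering call (diploid otherwise); adjacent atomic
    intervals with identical per-subject profiles are merged; components
    whose carrier frequency strictly exceeds ``min_frequency`` are returned.

    Overlapping same-subject calls with conflicting copy numbers raise an
    error naming the subject and the interval.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if subject_ids is None:
        called = sorted({c.subject_id for c in calls})
        if len(called) > cohort_size:
            raise ValueError(
                f"{len(called)} distinct called subjects exceed cohort_size "
                f"{cohort_size}")
        subject_ids = called + [f"UNCALLED{i:05d}"
                                for i in range(cohort_size - len(called))]
    if len(subject_ids) != cohort_size:
        raise ValueError("subject_ids length must equal cohort_size")
    idx = {s: i for i, s in enumerate(subject_ids)}
    for c in calls:
        if c.subject_id not in idx:
            raise ValueError(f"call subject {c.subject_id!r} not in cohort")

    out: list[CNVComponent] = []
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)

    for chrom in sorted(by_chrom):
        cc = by_chrom[chrom]
        # half-open (start-1, end] representation of 1-based inclusive calls
        bps = sorted({c.start_bp - 1 for c in cc} | {c.end_bp for c in cc})
        atoms = list(zip(bps[:-1], bps[1:]))       # (left, right] pairs
        profiles = np.full((len(atoms), cohort_size), DIPLOID, dtype=np.int16)
        for c in cc:
            j = idx[c.subject_id]
            for a, (lo, hi) in enumerate(atoms):
                if c.start_bp - 1 <= lo and hi <= c.end_bp:
                    prev = profiles[a, j]
                    if prev != DIPLOID and prev != c.copy_number:
                        raise ValueError(
                            f"conflicting copy numbers ({prev} vs "
                            f"{c.copy_number}) for subject {c.subject_id} on "
                            f"{chrom}:{lo + 1}-{hi}")
                    profiles[a, j] = c.copy_number
        # drop atoms nobody carries, merge adjacent identical profiles
        merged: list[tuple[int, int, np.ndarray]] = []
        for a, (lo, hi) in enumerate(atoms):
            if np.all(profiles[a] == DIPLOID):
                continue
            if merged and merged[-1][1] == lo and \
                    np.array_equal(merged[-1][2], profiles[a]):
                merged[-1] = (merged[-1][0], hi, merged[-1][2])
            else:
                merged.append((lo, hi, profiles[a]))
        for lo, hi, prof in merged:
            comp = CNVComponent(chrom=chrom, start_bp=lo + 1, end_bp=hi,
                                copy_number_by_subject=prof,
                                subject_ids=list(subject_ids))
            if comp.frequency > min_frequency:
                out.append(comp)
    return out


# ---------------------------------------------------------------------------
# rawcnv dialect (PennCNV-style call lists)

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")
_CN_RE = re.compile(r"^state\d+,cn=(?P<cn>\d+)$")


def parse_rawcnv(lines) -> list[CNVCall]:
    """Parse whitespace-delimited PennCNV-style call lines.

    Expected shape per line::

        chr3:6212573-6214264 numsnp=5 length=1,692 state2,cn=1 SAMPLE ...

    The parser extracts chrom/start/end, numsnp, copy number and the sample
    id (the token following the state field); ``length`` is tolerated and
    ignored (dialects disagree by one), ``conf=`` is optional.
    """
    calls = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        m = _REGION_RE.match(toks[0])
        if m is None:
            raise ValueError(f"unparseable region field: {toks[0]!r}")
        numsnp = 1
        cn = None
        sample = None
        conf = float("nan")
        for i, t in enumerate(toks[1:], start=1):
            if t.startswith("numsnp="):
                numsnp = int(t.split("=", 1)[1].replace(",", ""))
            elif _CN_RE.match(t):
                cn = int(_CN_RE.match(t).group("cn"))
                if sample is None and i + 1 < len(toks):
                    sample = toks[i + 1]
            elif t.startswith("conf="):
                conf = float(t.split("=", 1)[1])
        if cn is None or sample is None:
            raise ValueError(f"missing state/cn or sample field in: {line!r}")
        calls.append(CNVCall(
            subject_id=sample, chrom=m.group("chrom"),
            start_bp=int(m.group("start")), end_bp=int(m.group("end")),
            copy_number=cn, n_probes=numsnp, confidence=conf))
    return calls


def write_rawcnv(calls: list[CNVCall]) -> str:
    """Serialize calls in the rawcnv dialect (length written as end-start+1)."""
    lines = []
    for c in calls:
        length = c.end_bp - c.start_bp + 1
        fields = [
            f"{c.chrom}:{c.start_bp}-{c.end_bp}",
            f"numsnp={c.n_probes}",
            f"length={length:,}",
            f"state{ {0: 1, 1: 2, 3: 5, 4: 6}[c.copy_number] },"
            f"cn={c.copy_number}",
            c.subject_id,
        ]
        if np.isfinite(c.confidence):
            fields.append(f"conf={c.confidence:.3f}")
        lines.append(" ".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")
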
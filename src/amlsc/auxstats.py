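"""Auxiliary statistics: hashtag label refinement, limiting-dilution frequency
estimation, and gene-set kappa similarity.

Hashtag refinement cleans up droplet demultiplexing output on a 2-D embedding:
cells sharing a hashtag form a compact cluster, so a boundary around the
cluster's medoid (axis-aligned box of half-width equal to the 0.98 quantile of
member distances to the medoid) rescues hashtag-negative cells that fall
inside it and discards hashtag-labeled cells that fall far outside.

Limiting-dilution analysis estimates stem-cell frequency under the single-hit
Poisson model: a recipient fails to engraft with probability exp(-f * dose).
The MLE of f comes from a binomial GLM with complementary log-log link and
log-dose offset, the same formulation as the standard limiting-dilution
estimator; the confidence interval is Wald on log f.

The kappa score measures the chance-corrected overlap of two gene sets over a
common differential-expression universe (Cohen's kappa on the binary
membership vectors), used to cluster enriched terms by gene-sharing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

NEGATIVE = "Negative"
DOUBLET = "Doublet"


@dataclass
class HTOState:
    """Per-cell 2-D embedding, hashtag label and refinement provenance.

    ``initial_labels`` freezes the labeling the state was constructed with;
    rescue boundaries are always computed from it, which makes refinement
    idempotent.
    """

    embedding: np.ndarray  # n_cells x 2
    labels: np.ndarray  # hashtag id | Negative | Doublet
    provenance: np.ndarray = None  # original | rescued | discarded
    initial_labels: np.ndarray = None

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.embedding.ndim != 2 or self.embedding.shape[1] != 2:
            raise ValueError("embedding must be n_cells x 2")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.embedding):
            raise ValueError("one label per cell required")
        if self.provenance is None:
            self.provenance = np.full(len(self.labels), "original", dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if self.initial_labels is None:
            self.initial_labels = self.labels.copy()
        else:
            self.initial_labels = np.asarray(self.initial_labels, dtype=object)

    def hashtags(self) -> list[str]:
        """Hashtag ids in first-appearance order of the initial labeling."""
        seen: dict[str, None] = {}
        for lab in self.initial_labels:
            if lab not in (NEGATIVE, DOUBLET) and lab not in seen:
                seen[lab] = None
        return list(seen)


@dataclass
class HashtagBoundary:
    hashtag: str
    medoid: np.ndarray
    radius: float
    region: str

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - self.medoid
        if self.region == "box":
            return (np.abs(d[:, 0]) <= self.radius) & (np.abs(d[:, 1]) <= self.radius)
        return np.hypot(d[:, 0], d[:, 1]) <= self.radius


def _medoid(points: np.ndarray, chunk: int = 512) -> int:
    """Index of the point minimizing summed Euclidean distance to the others."""
    n = len(points)
    sums = np.empty(n)
    for start in range(0, n, chunk):
        block = points[start : start + chunk]
        d = np.hypot(
            block[:, None, 0] - points[None, :, 0],
            block[:, None, 1] - points[None, :, 1],
        )
        sums[start : start + chunk] = d.sum(axis=1)
    return int(np.argmin(sums))


def hashtag_boundary(
    state: HTOState, hashtag: str, quantile: float = 0.98, region: str = "box"
) -> HashtagBoundary:
    """Medoid and rescue radius for one hashtag's initially labeled cells."""
    idx = np.where(state.initial_labels == hashtag)[0]
    if len(idx) < 3:
        raise ValueError(f"hashtag {hashtag!r} has fewer than 3 cells")
    pts = state.embedding[idx]
    if np.ptp(pts, axis=0).max() == 0:
        warnings.warn(f"hashtag {hashtag!r}: all cells at one point; zero spread")
    medoid = pts[_medoid(pts)]
    dist = np.hypot(pts[:, 0] - medoid[0], pts[:, 1] - medoid[1])
    radius = float(np.quantile(dist, quantile))
    return HashtagBoundary(hashtag, medoid.copy(), radius, region)


def refine_hto(
    state: HTOState, quantile: float = 0.98, region: str = "box"
) -> tuple[HTOState, dict[str, HashtagBoundary]]:
    """Refine hashtag labels: discard outliers, rescue in-boundary Negatives.

    Hashtags are processed in input (first-appearance) order. For each
    hashtag H: cells currently labeled H outside H's boundary become Negative
    with provenance 'discarded'; Negative cells inside the boundary take
    label H with provenance 'rescued'. A cell rescued by an earlier hashtag is
    never relabeled by a later one. Doublet-labeled cells carry no hashtag
    attribution here and are left untouched. Returns a new state plus the
    boundary per hashtag; the operation is idempotent because boundaries
    derive from the initial labeling.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    if region not in ("box", "disc"):
        raise ValueError("region must be 'box' or 'disc'")
    new = HTOState(
        state.embedding.copy(),
        state.labels.copy(),
        state.provenance.copy(),
        state.initial_labels.copy(),
    )
    boundaries: dict[str, HashtagBoundary] = {}
    for h in new.hashtags():
        if (new.initial_labels == h).sum() < 3:
            warnings.warn(f"hashtag {h!r} has <3 cells; skipped")
            continue
        boundary = hashtag_boundary(new, h, quantile, region)
        boundaries[h] = boundary
        inside = boundary.contains(new.embedding)
        own = new.labels == h
        discard = own & ~inside
        new.labels[discard] = NEGATIVE
        new.provenance[discard] = "discarded"
        # discarded cells are dropped from analysis for good: never rescued
        rescue = (new.labels == NEGATIVE) & inside & (new.provenance != "discarded")
        new.labels[rescue] = h
        new.provenance[rescue] = "rescued"
    return new, boundaries


# ---------------------------------------------------------------------------
# limiting-dilution analysis


@dataclass
class LDAExperiment:
    """Dose/engraftment table: rows of (cells transplanted, mice tested,
    mice without engraftment)."""

    table: pd.DataFrame  # columns dose, n_tested, n_negative

    def __post_init__(self) -> None:
        t = self.table
        for col in ("dose", "n_tested", "n_negative"):
            if col not in t.columns:
                raise ValueError(f"LDA table missing column {col!r}")
        if (t["dose"] <= 0).any():
            raise ValueError("doses must be positive")
        if ((t["n_negative"] < 0) | (t["n_negative"] > t["n_tested"])).any():
            raise ValueError("need 0 <= n_negative <= n_tested")


@dataclass
class LDAFit:
    frequency: float  # stem-cell frequency per cell
    ci: tuple[float, float]
    confidence: float
    n_mice: int
    status: str = "ok"  # ok | all_negative | all_engrafted

    @property
    def one_in(self) -> float:
        """Frequency expressed as 1 cell in N."""
        return math.inf if self.frequency == 0 else 1.0 / self.frequency


def lda_log_likelihood(exp: LDAExperiment, f: float) -> float:
    """Single-hit binomial log-likelihood of frequency ``f``."""
    t = exp.table
    p_neg = np.exp(-f * t["dose"].to_numpy(dtype=float))
    n_neg = t["n_negative"].to_numpy(dtype=float)
    n_pos = (t["n_tested"] - t["n_negative"]).to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        ll = n_neg * np.log(p_neg) + n_pos * np.log1p(-p_neg)
    return float(np.where((n_pos == 0) & np.isneginf(ll), 0.0, ll).sum())


def estimate_frequency(exp: LDAExperiment, confidence: float = 0.95) -> LDAFit:
    """Maximum-likelihood stem-cell frequency under the single-hit model.

    P(no engraftment at dose d) = exp(-f d). Fit: binomial GLM, complementary
    log-log link, log-dose offset; CI: Wald on log f, back-transformed.
    All-negative tables give f = 0 with a one-sided upper bound; all-engrafted
    tables cannot bound f from above (no limiting dose was reached) and report
    a one-sided lower bound.
    """
    t = exp.table
    alpha = 1.0 - confidence
    n_mice = int(t["n_tested"].sum())
    total_cells = float((t["dose"] * t["n_tested"]).sum())
    n_engrafted = int((t["n_tested"] - t["n_negative"]).sum())

    if n_engrafted == 0:
        # P(all negative | f) = exp(-f * total cells); invert at alpha
        upper = -math.log(alpha) / total_cells
        return LDAFit(0.0, (0.0, upper), confidence, n_mice, status="all_negative")
    if int(t["n_negative"].sum()) == 0:
        # P(all engrafted | f) increasing in f; lower bound solves = alpha
        def log_p_all(f: float) -> float:
            return float(
                (t["n_tested"] * np.log1p(-np.exp(-f * t["dose"]))).sum()
            )

        lo_bracket = 1e-12
        hi_bracket = 1.0
        f_lower = optimize.brentq(
            lambda f: log_p_all(f) - math.log(alpha), lo_bracket, hi_bracket
        )
        return LDAFit(
            math.inf, (float(f_lower), math.inf), confidence, n_mice,
            status="all_engrafted",
        )

    engrafted = (t["n_tested"] - t["n_negative"]).to_numpy(dtype=float)
    negative = t["n_negative"].to_numpy(dtype=float)
    model = sm.GLM(
        np.column_stack([engrafted, negative]),
        np.ones((len(t), 1)),
        family=sm.families.Binomial(link=sm.families.links.CLogLog()),
        offset=np.log(t["dose"].to_numpy(dtype=float)),
    )
    res = model.fit()
    log_f = float(res.params[0])
    se = float(res.bse[0])
    z = stats.norm.ppf(1 - alpha / 2)
    return LDAFit(
        frequency=math.exp(log_f),
        ci=(math.exp(log_f - z * se), math.exp(log_f + z * se)),
        confidence=confidence,
        n_mice=n_mice,
    )


# ---------------------------------------------------------------------------
# gene-set kappa similarity


def kappa_score(set_a: set[str], set_b: set[str], universe: list[str]) -> float:
    """Cohen's kappa between two gene sets' membership over a DEG universe.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement of the
    binary membership vectors and p_e the chance agreement from marginals.
    If p_e = 1 (both sets empty or both equal the universe) kappa is 1 when
    the vectors are identical, otherwise undefined.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    uni = list(dict.fromkeys(universe))
    set_a, set_b = set(set_a), set(set_b)
    stray = (set_a | set_b) - set(uni)
    if stray:
        raise ValueError(f"gene(s) outside the universe: {sorted(stray)[:5]}")
    a = np.array([g in set_a for g in uni])
    b = np.array([g in set_b for g in uni])
    p_o = float((a == b).mean())
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        if np.array_equal(a, b):
            return 1.0
        raise ValueError("chance agreement is 1 but memberships differ")
    return (p_o - p_e) / (1 - p_e)
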
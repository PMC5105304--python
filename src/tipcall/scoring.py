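"""Candidate selection and five-feature probabilistic scoring.

The machine-learning route: every peak with junction-read evidence is a
candidate insertion site described by five features - peak width, peak
depth, the variant index (mean per-read mismatch fraction inside the
peak), polyA tail purity of the junction overhangs, and the junction-read
count. The model is trained within each sample: peaks at annotated fixed
L1 3' ends are the known positives; peaks far from any known element are
presumed negatives. A standardized, L2-regularized logistic regression
then assigns each candidate a probability of being a true insertion site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .align import ReadAlignment
from .errors import InvariantError
from .genome import L1Copy
from .peaks import JunctionRead, Peak
from .rng import substream

__all__ = [
    "FeatureVector",
    "CandidateCall",
    "Scorer",
    "polya_purity",
    "select_candidates",
    "compute_features",
    "peak_feature_table",
    "train_model",
    "score_candidates",
]

FEATURE_NAMES = (
    "peak_width",
    "peak_depth",
    "variant_index",
    "polya_purity",
    "junction_read_count",
)


@dataclass(frozen=True)
class FeatureVector:
    peak_width: float
    peak_depth: float
    variant_index: float
    polya_purity: float
    junction_read_count: float

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise InvariantError("features must be finite and >= 0")
        if not 0 <= self.polya_purity <= 1:
            raise InvariantError("polya_purity must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.peak_width,
                self.peak_depth,
                self.variant_index,
                self.polya_purity,
                self.junction_read_count,
            ],
            dtype=float,
        )


@dataclass
class CandidateCall:
    peak: Peak
    junction_reads: List[JunctionRead]
    features: Optional[FeatureVector] = None
    probability: Optional[float] = None
    label: str = "unlabeled"  # known_positive | presumed_negative | unlabeled
    sample_id: str = ""
    consensus: Optional[object] = None
    verdict: Optional[object] = None

    @property
    def boundary(self) -> int:
        if self.junction_reads:
            bs = sorted(j.boundary for j in self.junction_reads)
            return bs[len(bs) // 2]
        return self.peak.start

    @property
    def side(self) -> Optional[str]:
        if not self.junction_reads:
            return None
        sides = [j.side for j in self.junction_reads]
        return max(("left", "right"), key=lambda s: (sides.count(s), s == "left"))


def polya_purity(outward_overhang: str, dominance: float = 0.8) -> float:
    """Purity of the inferred tail: max A/T fraction over the longest
    mononucleotide-dominated prefix of the junction-outward overhang."""
    best = 0.0
    n_a = n_t = 0
    for i, base in enumerate(outward_overhang, start=1):
        n_a += base == "A"
        n_t += base == "T"
        frac = max(n_a, n_t) / i
        if frac >= dominance:
            best = frac
    return best


def select_candidates(
    peaks: Sequence[Peak],
    junction_map: Dict[Peak, List[JunctionRead]],
    layout: str = "single",
    sample_id: str = "",
) -> List[CandidateCall]:
    """Exactly the peaks with junction evidence become candidates.

    In paired layout a 'junction-containing read pair' is a pair with at
    least one junction mate; in single-end layout each junction read
    counts on its own.
    """
    out = []
    for p in sorted(peaks, key=lambda p: p.rank):
        jrs = junction_map.get(p, [])
        if layout == "paired":
            n_units = len({j.read_id.rsplit("/", 1)[0] for j in jrs})
        else:
            n_units = len(jrs)
        if n_units >= 1:
            out.append(CandidateCall(peak=p, junction_reads=list(jrs), sample_id=sample_id))
    return out


def _reads_in_peak(peak: Peak, alignments: Sequence[ReadAlignment]) -> List[ReadAlignment]:
    return [
        a
        for a in alignments
        if a.status == "unique"
        and a.chrom == peak.chrom
        and a.start <= peak.end
        and a.end >= peak.start
    ]


def compute_features(
    peak: Peak,
    alignments: Sequence[ReadAlignment],
    junction_reads: Sequence[JunctionRead],
) -> FeatureVector:
    """Five features for one peak."""
    reads = _reads_in_peak(peak, alignments)
    if not reads:
        raise InvariantError("a peak cannot contain zero reads")
    vi = float(
        np.mean([a.mismatches / (a.end - a.start + 1) for a in reads])
    )
    purity = (
        float(np.mean([polya_purity(j.overhang_outward) for j in junction_reads]))
        if junction_reads
        else 0.0
    )
    return FeatureVector(
        peak_width=float(peak.width),
        peak_depth=float(peak.max_coverage),
        variant_index=vi,
        polya_purity=purity,
        junction_read_count=float(len(junction_reads)),
    )


def peak_feature_table(
    peaks: Sequence[Peak],
    alignments: Sequence[ReadAlignment],
    junction_map: Dict[Peak, List[JunctionRead]],
) -> Dict[Peak, FeatureVector]:
    return {
        p: compute_features(p, alignments, junction_map.get(p, [])) for p in peaks
    }


def _distance(peak: Peak, copies: Sequence[L1Copy]) -> float:
    d = np.inf
    for c in copies:
        if c.chrom != peak.chrom:
            continue
        if peak.start <= c.end and peak.end >= c.start:
            return 0.0
        d = min(d, min(abs(peak.start - c.end), abs(c.start - peak.end)))
    return d


def _near_three_prime(peak: Peak, copies: Sequence[L1Copy], window: int) -> bool:
    for c in copies:
        if c.chrom == peak.chrom and abs_to_interval(c.three_prime_pos, peak) <= window:
            return True
    return False


def abs_to_interval(pos: int, peak: Peak) -> int:
    if peak.start <= pos <= peak.end:
        return 0
    return min(abs(pos - peak.start), abs(pos - peak.end))


@dataclass
class Scorer:
    scaler: StandardScaler
    model: LogisticRegression
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    n_positive: int = 0
    n_negative: int = 0

    @property
    def coefficients(self) -> Dict[str, float]:
        return dict(zip(self.feature_names, self.model.coef_[0]))

    def predict(self, features: Sequence[FeatureVector]) -> np.ndarray:
        X = np.vstack([f.as_array() for f in features])
        return self.model.predict_proba(self.scaler.transform(X))[:, 1]

    def export_text(self) -> str:
        lines = ["# logistic insertion-site scorer"]
        lines.append(f"intercept\t{self.model.intercept_[0]:.6g}")
        for name, coef in self.coefficients.items():
            lines.append(f"{name}\t{coef:.6g}")
        return "\n".join(lines) + "\n"


def train_model(
    candidates: Sequence[CandidateCall],
    known_l1: Sequence[L1Copy],
    negatives_per_positive: int = 1,
    seed: int = 0,
    peak_features: Optional[Dict[Peak, FeatureVector]] = None,
    positive_window: int = 500,
    negative_distance: int = 10_000,
    min_labeled: int = 5,
) -> Scorer:
    """Fit the within-sample scorer on known insertions.

    Positives: candidates whose peak lies within ``positive_window`` of an
    annotated fixed-L1 3' end. Negatives: peaks (candidate or not) farther
    than ``negative_distance`` from any annotated element, sampled at
    ``negatives_per_positive`` per positive with the given seed.
    """
    if peak_features is None:
        peak_features = {c.peak: c.features for c in candidates if c.features is not None}
    positives = [
        c for c in candidates if _near_three_prime(c.peak, known_l1, positive_window)
    ]
    pool = [
        (p, fv)
        for p, fv in sorted(peak_features.items(), key=lambda kv: (kv[0].chrom, kv[0].start))
        if _distance(p, known_l1) > negative_distance
    ]
    n_pos = len(positives)
    n_needed = max(min_labeled, min(len(pool), n_pos * negatives_per_positive))
    if n_pos < min_labeled or len(pool) < min_labeled:
        raise InvariantError(
            f"need >= {min_labeled} known-positive candidates and >= {min_labeled} "
            f"negative peaks; have {n_pos} and {len(pool)}"
        )
    rng = substream(seed, "negatives")
    idx = rng.choice(len(pool), size=min(n_needed, len(pool)), replace=False)
    negatives = [pool[i] for i in sorted(idx)]
    for c in positives:
        c.label = "known_positive"
    X, y = [], []
    for c in positives:
        fv = c.features if c.features is not None else peak_features[c.peak]
        X.append(fv.as_array())
        y.append(1)
    for _, fv in negatives:
        X.append(fv.as_array())
        y.append(0)
    X = np.vstack(X)
    y = np.array(y)
    scaler = StandardScaler().fit(X)
    model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    model.fit(scaler.transform(X), y)
    return Scorer(scaler=scaler, model=model, n_positive=n_pos, n_negative=len(negatives))


def score_candidates(
    scorer: Scorer, candidates: Sequence[CandidateCall]
) -> List[CandidateCall]:
    """Annotate candidates with probabilities; deterministic ordering."""
    if not candidates:
        return []
    feats = [
        c.features if c.features is not None else None for c in candidates
    ]
    if any(f is None for f in feats):
        raise InvariantError("all candidates need features before scoring")
    probs = scorer.predict(feats)
    out = []
    for c, p in zip(candidates, probs):
        c.probability = float(p)
        out.append(c)
    out.sort(key=lambda c: (-c.probability, c.peak.chrom, c.peak.start))
    return out
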
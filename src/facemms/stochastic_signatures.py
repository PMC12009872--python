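"""Gamma maximum-likelihood signatures and derived parameter spaces.

The two-parameter Gamma family (shape a, scale b, no location shift) is
fitted to positive MMS peak values by maximum likelihood.  The fitted pair
and its derived quantities form the stochastic signature:

    mean      Gamma_mu  = a * b
    sd        Gamma_sd  = sqrt(a) * b
    NSR       Gamma_sd / Gamma_mu = b     (noise-to-signal ratio)
    skewness  2 / sqrt(a)

A shape of 1 is the memoryless exponential; larger shapes approach the
Gaussian (skewness -> 0).  Signatures from the three face regions are
combined into NSR and skewness vectors whose Euclidean norms span the
scalar parameter plane.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from facemms import errors

MIN_SAMPLES = 30
_Z975 = 1.959963984540054  # 97.5% normal quantile


@dataclasses.dataclass
class GammaSignature:
    """MLE Gamma fit with asymptotic 95% confidence intervals."""

    shape: float
    scale: float
    ci95_shape: tuple[float, float]
    ci95_scale: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise errors.DomainError("shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.shape) * self.scale)

    @property
    def nsr(self) -> float:
        """Noise-to-signal ratio sd/mean; equals the scale b exactly."""
        return self.scale

    @property
    def skewness(self) -> float:
        return float(2.0 / np.sqrt(self.shape))


@dataclasses.dataclass
class SignatureSpacePoint:
    """One participant/task in the NSR-norm vs skewness-norm plane."""

    participant_id: str
    task: str
    signatures: dict[str, GammaSignature]
    nsr_vector: np.ndarray
    skew_vector: np.ndarray
    nsr_norm: float
    skew_norm: float


def _shape_equation(a: float, s: float) -> float:
    return np.log(a) - special.digamma(a) - s


def fit_gamma_mle(samples: np.ndarray) -> GammaSignature:
    """Fit Gamma(a, b) by maximum likelihood to positive samples.

    The profile likelihood in the shape reduces to the scalar equation
    log(a) - digamma(a) = log(mean) - mean(log), solved by bracketed root
    finding from the standard Minka/Choi-Wette starting point; the scale
    follows as b = mean/a.  95% CIs come from the inverse observed Fisher
    information.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if n < MIN_SAMPLES:
        raise errors.InsufficientDataError(
            f"need >= {MIN_SAMPLES} samples, got {n}"
        )
    if np.any(samples <= 0):
        raise errors.DomainError("Gamma MLE requires strictly positive samples")
    if np.var(samples) == 0:
        raise errors.DegenerateFitError("zero sample variance")

    mean = samples.mean()
    s = float(np.log(mean) - np.mean(np.log(samples)))
    if s <= 0:  # numerically degenerate (near-constant samples)
        raise errors.DegenerateFitError("log-moment gap non-positive")

    a0 = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    lo, hi = a0 / 8.0, a0 * 8.0
    for _ in range(60):
        if _shape_equation(lo, s) > 0 > _shape_equation(hi, s):
            break
        lo /= 2.0
        hi *= 2.0
    else:
        raise errors.FitFailureError(
            f"could not bracket shape root (s={s:.3g}, a0={a0:.3g})"
        )
    try:
        a = optimize.brentq(_shape_equation, lo, hi, args=(s,), xtol=1e-12)
    except ValueError as exc:
        raise errors.FitFailureError(f"shape solve failed: {exc}") from exc
    b = mean / a

    # Observed Fisher information of (a, b) at the MLE.
    info = n * np.array(
        [[special.polygamma(1, a), 1.0 / b], [1.0 / b, a / b**2]]
    )
    cov = np.linalg.inv(info)
    se_a, se_b = np.sqrt(np.diag(cov))
    return GammaSignature(
        shape=float(a),
        scale=float(b),
        ci95_shape=(float(a - _Z975 * se_a), float(a + _Z975 * se_a)),
        ci95_scale=(float(b - _Z975 * se_b), float(b + _Z975 * se_b)),
        n=n,
    )


def derive_nsr(sig: GammaSignature) -> float:
    """Noise-to-signal ratio: Gamma sd over Gamma mean, identically b."""
    return sig.nsr


def derive_skewness(sig: GammaSignature) -> float:
    """Gamma skewness 2/sqrt(a)."""
    return sig.skewness


def build_signature_space(
    signatures: dict[str, GammaSignature],
    participant_id: str = "",
    task: str = "resting",
    region_order: tuple[str, ...] = ("V1", "V2", "V3"),
) -> SignatureSpacePoint:
    """Assemble per-region signatures into NSR/skewness vectors and norms."""
    missing = [r for r in region_order if r not in signatures]
    if missing:
        raise errors.IncompleteSignatureError(
            f"missing region signature(s): {missing}"
        )
    nsr = np.array([signatures[r].nsr for r in region_order])
    skew = np.array([signatures[r].skewness for r in region_order])
    return SignatureSpacePoint(
        participant_id=participant_id,
        task=task,
        signatures=dict(signatures),
        nsr_vector=nsr,
        skew_vector=skew,
        nsr_norm=float(np.linalg.norm(nsr)),
        skew_norm=float(np.linalg.norm(skew)),
    )


def pairwise_ranksum(
    grid: dict[tuple, np.ndarray],
    pairs: list[tuple[tuple, tuple]] | None = None,
    adjust: bool = False,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) tests between cells.

    ``grid`` maps a cell key, e.g. (group, task, region), to its sample
    values.  By default every unordered pair of cells is tested; pass
    ``pairs`` to restrict.  No multiplicity correction unless ``adjust``
    (Benjamini-Hochberg) is requested.
    """
    if pairs is None:
        pairs = list(itertools.combinations(sorted(grid), 2))
    rows = []
    for ka, kb in pairs:
        xa, xb = np.asarray(grid[ka]), np.asarray(grid[kb])
        if xa.shape[0] < min_samples or xb.shape[0] < min_samples:
            warnings.warn(f"skipping underpowered pair {ka} vs {kb}")
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append((ka, kb, float(res.statistic), float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["cell_a", "cell_b", "statistic", "p"])
    if adjust and len(table):
        table["p_adj"] = stats.false_discovery_control(table["p"], method="bh")
    return table


def signature_table(
    signatures: dict[tuple[str, str, str], GammaSignature]
) -> pd.DataFrame:
    """Flatten {(participant, task, region): signature} into a table."""
    rows = []
    for (pid, task, region), sig in signatures.items():
        rows.append(
            (
                pid, task, region, sig.shape, sig.scale,
                sig.ci95_shape[0], sig.ci95_shape[1],
                sig.ci95_scale[0], sig.ci95_scale[1],
                sig.mean, sig.nsr, sig.skewness, sig.n,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "task", "region", "a", "b",
            "a_lo", "a_hi", "b_lo", "b_hi",
            "gamma_mean", "nsr", "skewness", "n",
        ],
    )
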
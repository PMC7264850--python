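"""Geographic cline curve families and their likelihoods.

A geographic cline describes how an allele frequency or a standardized
trait mean changes along a one-dimensional transect through a hybrid
zone.  Three nested sigmoid families are provided:

* model I  — a plain logistic step with a center ``c`` and width ``w``
  (width is the inverse of the maximum slope, so the logistic core is
  ``Phi(d) = 1 / (1 + exp(-4 (d - c) / w))``);
* model II — the same core with symmetric exponential introgression
  tails attached at distance ``delta`` either side of the center;
* model III — independent left and right tails (asymmetric
  introgression).

Tails are parameterized by an attachment distance ``delta`` (m, >= 0)
and a slope ratio ``tau`` in (0, 1]: the tail leaves the attachment
point with ``tau`` times the sigmoid's slope and decays exponentially
toward the parental value, so ``tau = 1`` joins smoothly (C1) and small
``tau`` gives long, shallow tails.  The curve is always continuous (C0)
at the attachment points.

A null model — a straight line between the two transect endpoints — is
included for model comparison.  All curves are mapped onto the data
scale by the two asymptotic values ``pmin`` (western end) and ``pmax``
(eastern end); decreasing clines are encoded by ``pmin > pmax``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClineModel",
    "FrequencyBinTable",
    "TraitBinTable",
    "evaluate",
    "loglik_frequency",
    "loglik_trait",
    "standardize_trait",
    "delta_p",
    "MODEL_TYPES",
    "N_FREE_PARAMS",
    "FREQ_EPS",
]

MODEL_TYPES = ("null", "I", "II", "III")

#: free parameters per model type: null counts its two endpoint values,
#: the sigmoid models count (c, w, pmin, pmax) plus tail parameters.
N_FREE_PARAMS = {"null": 2, "I": 4, "II": 6, "III": 8}

#: clamp applied to fitted frequencies inside the binomial likelihood so
#: the log stays finite when a cline hits 0 or 1 (chloroplast-style
#: fixed ends make this reachable).
FREQ_EPS = 1e-6


@dataclass(frozen=True)
class ClineModel:
    """A parameterized cline curve mapping transect distance to a value.

    Parameters
    ----------
    model_type
        One of ``"null"``, ``"I"``, ``"II"``, ``"III"``.
    center, width
        Location (m) of the inflection point and 1/max-slope width (m).
        Ignored by the null model.
    pmin, pmax
        Asymptotic values at the western (negative-distance) and eastern
        ends.  ``pmin > pmax`` encodes a decreasing cline.
    delta_l, tau_l, delta_r, tau_r
        Tail attachment distances (m) and slope ratios.  Model II uses
        the left pair for both sides; model I ignores all four.
    d_min, d_max
        Transect anchors for the null model's straight line.
    """

    model_type: str
    center: float = 0.0
    width: float = 1.0
    pmin: float = 0.0
    pmax: float = 1.0
    delta_l: float = 0.0
    tau_l: float = 1.0
    delta_r: float = 0.0
    tau_r: float = 1.0
    d_min: float | None = None
    d_max: float | None = None

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"unknown model_type {self.model_type!r}")
        if self.model_type != "null" and not self.width > 0:
            raise ValueError("width must be > 0")
        for nm in ("center", "width", "pmin", "pmax", "delta_l", "tau_l", "delta_r", "tau_r"):
            v = getattr(self, nm)
            if not math.isfinite(v):
                raise ValueError(f"non-finite {nm}")
        if self.model_type in ("II", "III"):
            if self.delta_l < 0 or not (0.0 < self.tau_l <= 1.0):
                raise ValueError("tail requires delta >= 0 and tau in (0, 1]")
        if self.model_type == "III":
            if self.delta_r < 0 or not (0.0 < self.tau_r <= 1.0):
                raise ValueError("tail requires delta >= 0 and tau in (0, 1]")
        if self.model_type == "null":
            if self.d_min is None or self.d_max is None:
                raise ValueError("null model needs d_min and d_max anchors")
            if not (math.isfinite(self.d_min) and math.isfinite(self.d_max)):
                raise ValueError("non-finite null anchors")

    @property
    def n_free_params(self) -> int:
        return N_FREE_PARAMS[self.model_type]


def _sigmoid_core(d: np.ndarray, c: float, w: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(-4.0 * (d - c) / w, -700, 700)))


def phi(
    d: np.ndarray | float,
    c: float,
    w: float,
    model_type: str = "I",
    delta_l: float = 0.0,
    tau_l: float = 1.0,
    delta_r: float = 0.0,
    tau_r: float = 1.0,
) -> np.ndarray:
    """Unit-scale cline shape in (0, 1), with optional exponential tails.

    Tail construction: at the left attachment point ``a_L = c - delta_l``
    the curve continues for ``d <= a_L`` as
    ``Phi(a_L) * exp(lam_L (d - a_L))`` with decay rate
    ``lam_L = tau_l * Phi'(a_L) / Phi(a_L)``; mirrored on the right with
    ``1 - (1 - Phi(a_R)) * exp(-lam_R (d - a_R))``.  Both joins are exact
    (C0), and C1 when tau = 1.
    """
    d = np.asarray(d, dtype=float)
    out = _sigmoid_core(d, c, w)
    if model_type in ("II", "III"):
        if model_type == "II":
            delta_r, tau_r = delta_l, tau_l
        a_l = c - delta_l
        phi_l = float(_sigmoid_core(np.asarray(a_l), c, w))
        # Phi'(a) = (4/w) Phi (1-Phi)  =>  lam_L = tau * (4/w) * (1 - Phi(a_L))
        lam_l = tau_l * (4.0 / w) * (1.0 - phi_l)
        left = d <= a_l
        if np.any(left):
            # exponent is <= 0 inside the tail region; clip keeps the
            # discarded branch of np.where from overflowing
            expo = np.clip(lam_l * (d - a_l), -745.0, 0.0)
            out = np.where(left, phi_l * np.exp(expo), out)
        a_r = c + delta_r
        phi_r = float(_sigmoid_core(np.asarray(a_r), c, w))
        lam_r = tau_r * (4.0 / w) * phi_r
        right = d >= a_r
        if np.any(right):
            expo = np.clip(-lam_r * (d - a_r), -745.0, 0.0)
            out = np.where(right, 1.0 - (1.0 - phi_r) * np.exp(expo), out)
    return out


def evaluate(model: ClineModel, d: np.ndarray | float) -> np.ndarray | float:
    """Expected frequency / standardized trait value at distance ``d`` (m).

    The sigmoid families return ``pmin + (pmax - pmin) * Phi(d)``; the
    null model returns the straight line through ``(d_min, pmin)`` and
    ``(d_max, pmax)`` (a flat line when the anchors coincide).
    """
    scalar = np.isscalar(d)
    arr = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite distance")
    if model.model_type == "null":
        span = model.d_max - model.d_min
        if span == 0:
            vals = np.full_like(arr, 0.5 * (model.pmin + model.pmax))
        else:
            vals = model.pmin + (model.pmax - model.pmin) * (arr - model.d_min) / span
    else:
        shape = phi(
            arr,
            model.center,
            model.width,
            model.model_type,
            model.delta_l,
            model.tau_l,
            model.delta_r,
            model.tau_r,
        )
        vals = model.pmin + (model.pmax - model.pmin) * shape
    return float(vals) if scalar else vals


def delta_p(model: ClineModel) -> float:
    """|pmax - pmin|: how differentiated the character is across the zone."""
    return abs(model.pmax - model.pmin)


# ---------------------------------------------------------------------------
# Bin tables


@dataclass
class FrequencyBinTable:
    """Per-bin allele counts along the transect.

    ``n_alleles`` is 2x the genotyped trees for nuclear SNPs and 1x for
    the haploid chloroplast; ``count`` is the focal-allele tally.
    """

    distance: np.ndarray
    n_alleles: np.ndarray
    count: np.ndarray
    bin_id: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=int)
        self.count = np.asarray(self.count, dtype=int)
        if not (len(self.distance) == len(self.n_alleles) == len(self.count)):
            raise ValueError("ragged bin table")
        if len(self.distance) == 0:
            raise ValueError("empty bin table")
        if np.any(self.n_alleles <= 0):
            raise ValueError("n_alleles must be positive")
        if np.any((self.count < 0) | (self.count > self.n_alleles)):
            raise ValueError("count outside [0, n_alleles]")
        if not self.bin_id:
            self.bin_id = [f"bin{i:02d}" for i in range(len(self.distance))]

    def __len__(self) -> int:
        return len(self.distance)

    @property
    def frequency(self) -> np.ndarray:
        return self.count / self.n_alleles

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_id": self.bin_id,
                "distance_m": self.distance,
                "n": self.n_alleles,
                "count": self.count,
            }
        )


@dataclass
class TraitBinTable:
    """Per-bin mean and variance of a standardized trait."""

    distance: np.ndarray
    n: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    bin_id: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if not (len(self.distance) == len(self.n) == len(self.mean) == len(self.variance)):
            raise ValueError("ragged bin table")
        if len(self.distance) == 0:
            raise ValueError("empty bin table")
        if np.any(self.n < 1):
            raise ValueError("bin n must be >= 1")
        if np.any(self.variance < 0):
            raise ValueError("negative variance")
        if not self.bin_id:
            self.bin_id = [f"bin{i:02d}" for i in range(len(self.distance))]

    def __len__(self) -> int:
        return len(self.distance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_id": self.bin_id,
                "distance_m": self.distance,
                "n": self.n,
                "mean": self.mean,
                "variance": self.variance,
            }
        )


# ---------------------------------------------------------------------------
# Likelihoods


def loglik_frequency(model: ClineModel, table: FrequencyBinTable) -> float:
    """Binomial log-likelihood of per-bin allele counts under ``model``.

    The combinatorial constant is omitted (it is constant across models
    on fixed data).  Fitted frequencies are clamped to
    ``[FREQ_EPS, 1 - FREQ_EPS]``.
    """
    p = np.clip(evaluate(model, table.distance), FREQ_EPS, 1.0 - FREQ_EPS)
    k = table.count
    n = table.n_alleles
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def loglik_trait(
    model: ClineModel, table: TraitBinTable, pooled_fallback: bool = True
) -> float:
    """Gaussian log-likelihood of per-bin trait means under ``model``.

    The bin mean is modeled as Normal(mu(d_i), v_i / n_i) where v_i is
    the within-bin variance.  Bins with n < 2 (or zero variance) fall
    back to the pooled within-bin variance when ``pooled_fallback`` is
    enabled, otherwise they raise.
    """
    v = table.variance.astype(float).copy()
    bad = (table.n < 2) | (v <= 0)
    if np.any(bad):
        if not pooled_fallback:
            raise ValueError("bin with n < 2 or zero variance and pooled fallback disabled")
        good = ~bad
        if not np.any(good):
            raise ValueError("no bin provides a usable variance for pooling")
        dof = table.n[good] - 1
        pooled = float(np.sum(v[good] * dof) / np.sum(dof))
        if pooled <= 0:
            raise ValueError("pooled within-bin variance is zero")
        v[bad] = pooled
    mu = np.asarray(evaluate(model, table.distance), dtype=float)
    se2 = v / table.n
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * se2) - (table.mean - mu) ** 2 / (2.0 * se2)))


# ---------------------------------------------------------------------------
# Trait standardization


@dataclass(frozen=True)
class TraitScaler:
    """Records (transform, min, max) so standardized values invert exactly."""

    transform: str
    lo: float
    hi: float
    constant: bool = False

    def inverse(self, values: np.ndarray | float) -> np.ndarray | float:
        arr = np.asarray(values, dtype=float)
        raw = self.lo if self.constant else self.lo + arr * (self.hi - self.lo)
        raw = np.asarray(raw, dtype=float)
        if self.transform == "log":
            raw = np.exp(raw)
        elif self.transform == "sqrt":
            raw = raw**2
        return float(raw) if np.isscalar(values) else raw


def standardize_trait(
    values: Sequence[float] | np.ndarray,
    transform: str = "none",
    ids: Iterable[str] | None = None,
) -> tuple[np.ndarray, TraitScaler]:
    """Transform then min-max scale trait values onto [0, 1].

    ``transform`` is one of ``none``, ``log``, ``sqrt`` (tree height is
    conventionally log-transformed and trunk height square-root
    transformed before cline fitting).  Constant input maps to all 0.5
    with a warning.  Returns the scaled values and a :class:`TraitScaler`
    for inversion.
    """
    if transform not in ("none", "log", "sqrt"):
        raise ValueError(f"unknown transform {transform!r}")
    arr = np.asarray(values, dtype=float)
    id_list = list(ids) if ids is not None else [str(i) for i in range(len(arr))]
    if transform == "log":
        bad = np.where(~(arr > 0))[0]
        if bad.size:
            raise ValueError(f"log transform needs positive values; offending id {id_list[bad[0]]}")
        arr = np.log(arr)
    elif transform == "sqrt":
        bad = np.where(arr < 0)[0]
        if bad.size:
            raise ValueError(f"sqrt transform needs nonnegative values; offending id {id_list[bad[0]]}")
        arr = np.sqrt(arr)
    lo, hi = float(np.min(arr)), float(np.max(arr))
    if hi == lo:
        warnings.warn("constant trait: standardized to 0.5 everywhere", stacklevel=2)
        return np.full_like(arr, 0.5), TraitScaler(transform, lo, hi, constant=True)
    return (arr - lo) / (hi - lo), TraitScaler(transform, lo, hi)
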
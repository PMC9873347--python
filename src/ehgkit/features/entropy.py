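"""Entropy-family window features.

Six estimator families, 18 features per window:

* Sample entropy (SampEn): m=2, tolerance r = 0.15 * SD of the window
  (the usual relative convention), Chebyshev distance, self-matches
  excluded.
* Fuzzy entropy (FuzzEn): m=2, absolute tolerance r=0.0077, exponential
  membership exp(-(d/r)^n) with n=3, in two variants — *local* removes each
  template's own mean before the distance, *global* removes the whole-window
  mean.  The printed tolerance is far below any plausible relative
  coefficient, so it is applied as-is on the (record-level z-scored) window.
* Permutation entropy (PerEn): ordinal patterns of order 3 at delay 2
  ("d=2, pi=3" read as delay 2, pattern length 3), ties broken by order of
  appearance, normalized by ln(3!).
* Dispersion entropy (DispEn): linear min-max mapping into c=3 classes,
  embedding m=2 at delay 1, normalized by ln(c^m).
* Bubble entropy (bEn): Renyi-2 entropy of bubble-sort swap counts at
  embedding orders m+1 and m, normalized by ln((m+1)/(m-1)); m defaults
  to 10 as recommended for series of this length.
* Phase entropy (PhEn): normalized Shannon entropy of the angular
  distribution of second-order difference-plot points over k equal sectors,
  for k = 2, 4, ..., 24 (twelve features).  Sector occupancy is by point
  count; origin points are dropped.

Natural logarithms throughout.  The O(N^2) pair scans (SampEn, FuzzEn) are
numba-compiled with early abort on the Chebyshev distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

#: PhEn sector counts analysed: k = 2..24 in steps of 2.
PHEN_KS = tuple(range(2, 25, 2))

#: Value returned when a count-based entropy is formally infinite.
INF_SENTINEL = float("inf")


@dataclass(frozen=True)
class EntropyParams:
    """Internal parameters of the entropy estimators."""

    sampen_m: int = 2
    sampen_r: float = 0.15          # relative to window SD
    fuzzen_m: int = 2
    fuzzen_r: float = 0.0077        # absolute
    fuzzen_n: float = 3.0
    peren_order: int = 3
    peren_delay: int = 2
    dispen_m: int = 2
    dispen_c: int = 3
    ben_m: int = 10
    phen_ks: tuple[int, ...] = PHEN_KS

    def __post_init__(self) -> None:
        if min(self.sampen_m, self.fuzzen_m, self.dispen_m) < 1:
            raise ValueError("embedding dimensions must be >= 1")
        if self.sampen_r <= 0 or self.fuzzen_r <= 0:
            raise ValueError("tolerances must be positive")
        if self.dispen_c < 2:
            raise ValueError("dispersion class count c must be >= 2")
        if len(set(self.phen_ks)) != len(self.phen_ks):
            raise ValueError("PhEn k values must be distinct")
        if any(k < 2 or k % 2 for k in self.phen_ks):
            raise ValueError("PhEn k values must be even and >= 2")


# ---------------------------------------------------------------------------
# sample entropy

@njit(cache=True)
def _sampen_counts(x, m, r):
    n = x.size
    nt = n - m  # templates i = 0..nt-1; component i+m exists for all
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(x: np.ndarray, m: int = 2, r_coeff: float = 0.15) -> float:
    """SampEn = -ln(A/B), Chebyshev distance, tolerance r = r_coeff * SD.

    A constant series gives 0 (all templates match at r = 0 with <=); if no
    (m+1)-matches exist the formally infinite value is returned as ``inf``.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size < m + 2:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    r = r_coeff * float(np.std(x))
    a, b = _sampen_counts(x, m, r)
    if b == 0 or a == 0:
        return INF_SENTINEL
    if a == b:
        return 0.0
    return float(-math.log(a / b))


# ---------------------------------------------------------------------------
# fuzzy entropy

@njit(cache=True, fastmath=True)
def _fuzzy_phi(templates, r, nexp):
    nt, m = templates.shape
    # memberships below exp(-745) underflow to zero; skip such pairs early
    cut = r * (745.0 ** (1.0 / nexp))
    int_n = int(nexp) if nexp == int(nexp) else 0
    total = 0.0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            skip = False
            for k in range(m):
                diff = abs(templates[i, k] - templates[j, k])
                if diff > d:
                    d = diff
                    if d > cut:
                        skip = True
                        break
            if not skip:
                u = d / r
                if int_n > 0:  # repeated multiplication beats pow()
                    arg = 1.0
                    for _ in range(int_n):
                        arg *= u
                else:
                    arg = u ** nexp
                total += math.exp(-arg)
    return total / (nt * (nt - 1) / 2.0)


def _fuzzy_templates(x: np.ndarray, m: int, n_templates: int,
                     variant: str) -> np.ndarray:
    idx = np.arange(n_templates)[:, None] + np.arange(m)[None, :]
    t = x[idx]
    if variant == "local":
        t = t - t.mean(axis=1, keepdims=True)
    return np.ascontiguousarray(t)


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float = 0.0077,
                  n: float = 3.0, variant: str = "local") -> float:
    """FuzzEn = ln(phi_m) - ln(phi_{m+1}) with exponential membership.

    ``variant='local'`` demeans each template by its own mean,
    ``variant='global'`` demeans the whole window once.
    """
    if variant not in ("local", "global"):
        raise ValueError("variant must be 'local' or 'global'")
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 2:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    if variant == "global":
        x = x - x.mean()
    n_templates = x.size - m  # same count at both orders
    phi = []
    for order in (m, m + 1):
        t = _fuzzy_templates(x, order, n_templates, variant)
        phi.append(max(_fuzzy_phi(t, r, n), 1e-300))
    return float(math.log(phi[0]) - math.log(phi[1]))


# ---------------------------------------------------------------------------
# permutation entropy

def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 2,
                        normalize: bool = True) -> float:
    """Shannon entropy of ordinal patterns (ties by order of appearance)."""
    x = np.asarray(x, dtype=np.float64)
    min_len = (order - 1) * delay + 2  # at least two ordinal patterns
    if x.size < min_len:
        raise ValueError(
            f"series of length {x.size} too short for order={order}, "
            f"delay={delay} (need >= {min_len})")
    n_vec = x.size - (order - 1) * delay
    idx = np.arange(n_vec)[:, None] + delay * np.arange(order)[None, :]
    # stable argsort realizes the order-of-appearance tie-break
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = patterns @ (order ** np.arange(order))
    counts = np.bincount(codes)
    p = counts[counts > 0] / n_vec
    h = float(-(p * np.log(p)).sum())
    if normalize:
        h /= math.log(math.factorial(order))
    return h


# ---------------------------------------------------------------------------
# dispersion entropy

def dispersion_entropy(x: np.ndarray, m: int = 2, c: int = 3) -> float:
    """Normalized Shannon entropy of dispersion patterns (linear mapping).

    Samples are binned into classes 1..c by linear min-max scaling and
    embedded at delay 1; a zero-range window maps to a single class and
    returns 0 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 1:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    rng = x.max() - x.min()
    if rng == 0:
        return 0.0
    classes = np.minimum((c * (x - x.min()) / rng).astype(np.int64), c - 1)
    n_vec = x.size - m + 1
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :]
    codes = classes[idx] @ (c ** np.arange(m))
    counts = np.bincount(codes)
    p = counts[counts > 0] / n_vec
    return float(-(p * np.log(p)).sum() / math.log(c ** m))


# ---------------------------------------------------------------------------
# bubble entropy

def _swap_count_entropy(x: np.ndarray, m: int) -> float:
    """Renyi-2 entropy of bubble-sort swap counts of m-embedded vectors."""
    n_vec = x.size - m + 1
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :]
    emb = x[idx]
    swaps = np.zeros(n_vec, dtype=np.int64)
    for k in range(m - 1):
        for l in range(k + 1, m):
            swaps += emb[:, k] > emb[:, l]
    counts = np.bincount(swaps)
    p = counts[counts > 0] / n_vec
    return float(-math.log(np.sum(p * p)))


def bubble_entropy(x: np.ndarray, m: int = 10) -> float:
    """bEn = (H_{m+1} - H_m) / ln((m+1)/(m-1)), H = Renyi-2 swap entropy."""
    if m < 2:
        raise ValueError("bubble entropy requires m >= 2")
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 2:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    h_m = _swap_count_entropy(x, m)
    h_m1 = _swap_count_entropy(x, m + 1)
    return float((h_m1 - h_m) / math.log((m + 1) / (m - 1)))


# ---------------------------------------------------------------------------
# phase entropy

def _sodp_angles(x: np.ndarray) -> np.ndarray:
    """Angles of second-order difference-plot points, origin points dropped."""
    d = np.diff(np.asarray(x, dtype=np.float64))
    xs, ys = d[:-1], d[1:]
    keep = ~((xs == 0) & (ys == 0))
    xs, ys = xs[keep], ys[keep]
    if xs.size == 0:
        raise ValueError("degenerate signal: all difference-plot points at "
                         "the origin")
    return np.mod(np.arctan2(ys, xs), 2.0 * np.pi)


def phase_entropy(x: np.ndarray, k: int) -> float:
    """Normalized angular entropy of the second-order difference plot.

    The plane is cut into k equal sectors starting at angle 0; sector
    probabilities come from point counts; PhEn = -sum p ln p / ln k in [0,1].
    """
    if k < 2 or k % 2:
        raise ValueError("k must be even and >= 2")
    x = np.asarray(x, dtype=np.float64)
    if x.size < 4:
        raise ValueError("series must have at least 4 samples")
    theta = _sodp_angles(x)
    sectors = np.minimum((theta / (2.0 * np.pi / k)).astype(np.int64), k - 1)
    counts = np.bincount(sectors, minlength=k)
    p = counts[counts > 0] / theta.size
    return float(-(p * np.log(p)).sum() / math.log(k))


def phen_profile(x: np.ndarray, ks: tuple[int, ...] = PHEN_KS
                 ) -> dict[str, float]:
    """PhEn at each sector count in ``ks`` -> {'PhEn_k2': ..., ...}."""
    if len(set(ks)) != len(ks):
        raise ValueError("duplicate k values in ks")
    theta = _sodp_angles(np.asarray(x, dtype=np.float64))
    out = {}
    for k in ks:
        if k < 2 or k % 2:
            raise ValueError("k must be even and >= 2")
        sectors = np.minimum((theta / (2.0 * np.pi / k)).astype(np.int64),
                             k - 1)
        counts = np.bincount(sectors, minlength=k)
        p = counts[counts > 0] / theta.size
        out[f"PhEn_k{k}"] = float(-(p * np.log(p)).sum() / math.log(k))
    return out
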
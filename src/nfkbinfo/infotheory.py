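"""Distribution-level information metrics for dose-response panels.

This module quantifies how well a population of single-cell readouts resolves
a panel of stimulus doses.  Two complementary measures are provided:

* the two-sample Kolmogorov-Smirnov (KS) distance together with its
  decision-theoretic decomposition into miss and false-alarm probabilities
  (``1 - KS = p_miss + p_false_alarm`` at the optimal threshold), and

* mutual information (MI, in bits) between a discrete dose and a continuous
  scalar readout, estimated with Kozachenko-Leonenko k-nearest-neighbour
  differential entropies and maximized over the input prior to approximate
  the channel capacity.

Analytic oracles for Gaussian readout distributions (closed-form KS, MI by
adaptive quadrature) support validation of the sample-based estimators.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import digamma, erf

__all__ = [
    "Sample",
    "DosePanel",
    "KSResult",
    "DiscernibilityProfile",
    "GaussianSpec",
    "PriorVector",
    "MIEstimate",
    "ks_distance",
    "error_probability",
    "ks_from_error_rates",
    "gaussian_ks_closed_form",
    "discernibility_profile",
    "mi_given_priors",
    "maximize_mi",
    "blahut_arimoto_mi",
    "gaussian_mi_quadrature",
    "maximize_mi_gaussian",
    "validate_estimator",
    "sqrt_mi_ks_correlation",
]

LN2 = math.log(2.0)

# Relative magnitude of the deterministic tie-breaking jitter added to
# readouts before kNN distance computations (standard Kraskov practice).
JITTER_REL = 1e-10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sample:
    """A population of scalar single-cell readouts at one dose.

    Parameters
    ----------
    values : array-like of float
        One readout per cell (arbitrary units).  Must be non-empty and finite.
    label : object
        Dose identifier (e.g. TNF concentration in ng/ml).
    """

    values: np.ndarray
    label: object = None

    def __init__(self, values, label=None):
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("Sample must contain at least one value")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Sample values must be finite")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "label", label)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DosePanel:
    """Ordered stimulus doses with one readout :class:`Sample` per dose."""

    doses: tuple
    samples: tuple

    def __init__(self, doses: Sequence[float], samples: Sequence[Sample]):
        doses = tuple(float(d) for d in doses)
        samples = tuple(samples)
        if len(doses) < 2:
            raise ValueError("DosePanel requires at least 2 doses")
        if len(doses) != len(samples):
            raise ValueError("doses and samples must have equal length")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        samples = tuple(
            s if isinstance(s, Sample) else Sample(s, label=d)
            for d, s in zip(doses, samples)
        )
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "samples", samples)

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    @property
    def n_per_dose(self) -> tuple:
        return tuple(len(s) for s in self.samples)

    def subset(self, indices: Sequence[int]) -> "DosePanel":
        """Panel restricted to the doses at the given positions."""
        return DosePanel(
            [self.doses[i] for i in indices], [self.samples[i] for i in indices]
        )

    # -- I/O --------------------------------------------------------------
    def to_frame(self, node: str | None = None) -> pd.DataFrame:
        rows = []
        for d, s in zip(self.doses, self.samples):
            df = pd.DataFrame({"dose": d, "readout": s.values})
            df["cell_id"] = np.arange(len(s))
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        if node is not None:
            out["node"] = node
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, node: str | None = None) -> "DosePanel":
        if node is not None:
            if "node" not in df.columns:
                raise ValueError("frame has no 'node' column")
            df = df[df["node"] == node]
        if df.empty:
            raise ValueError("no rows for requested panel")
        doses = np.sort(df["dose"].unique())
        samples = [
            Sample(df.loc[df["dose"] == d, "readout"].to_numpy(), label=d)
            for d in doses
        ]
        return cls(doses, samples)

    def to_csv(self, path, node: str | None = None) -> None:
        self.to_frame(node=node).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, node: str | None = None) -> "DosePanel":
        return cls.from_frame(pd.read_csv(path), node=node)


@dataclass(frozen=True)
class KSResult:
    """KS distance with its optimal-threshold error decomposition.

    ``p_miss + p_false_alarm == 1 - ks`` holds exactly on the empirical CDFs
    at the returned threshold, and the error probability for equiprobable
    doses is ``p_error = (1 - ks) / 2``.
    """

    ks: float
    threshold: float
    p_miss: float
    p_false_alarm: float
    p_error: float


@dataclass(frozen=True)
class DiscernibilityProfile:
    """Adjacent-dose discernibility C(d) and sensitivity S(d).

    ``c_values`` are KS distances per unit log-dose; ``s_values`` are mean
    readout shifts per unit log-dose.  Pairs involving a zero dose have no
    defined log-spacing; their ``c``/``s`` entries are NaN while the KS
    distance is still reported.
    """

    dose_pairs: tuple
    ks_values: np.ndarray
    c_values: np.ndarray
    s_values: np.ndarray


@dataclass(frozen=True)
class GaussianSpec:
    """Means and standard deviations of per-dose Gaussian readouts."""

    means: np.ndarray
    sds: np.ndarray

    def __init__(self, means, sds):
        means = np.asarray(means, dtype=float).ravel()
        sds = np.asarray(sds, dtype=float).ravel()
        if means.size != sds.size:
            raise ValueError("means and sds must have equal length")
        if np.any(sds <= 0):
            raise ValueError("sds must be strictly positive")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    @property
    def n_components(self) -> int:
        return self.means.size


@dataclass(frozen=True)
class PriorVector:
    """Probability vector over doses (simplex element)."""

    p: np.ndarray

    def __init__(self, p):
        arr = np.asarray(p, dtype=float).ravel()
        if np.any(arr < 0):
            raise ValueError("prior probabilities must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError("prior probabilities must sum to 1 (within 1e-12)")
        object.__setattr__(self, "p", arr)

    @classmethod
    def uniform(cls, n: int) -> "PriorVector":
        return cls(np.full(n, 1.0 / n))

    def __len__(self) -> int:
        return self.p.size


@dataclass(frozen=True)
class MIEstimate:
    """Mutual information (bits) for a prior over doses."""

    mi_bits: float
    priors: PriorVector
    k_neighbors: int
    n_per_dose: tuple
    converged: bool = True
    n_iterations: int = 0

    def to_json(self, **extra) -> str:
        payload = {
            "mi_bits": self.mi_bits,
            "priors": list(self.priors.p),
            "k_neighbors": self.k_neighbors,
            "n_per_dose": list(self.n_per_dose),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }
        payload.update(extra)
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov machinery
# ---------------------------------------------------------------------------


def ks_distance(a: Sample | Iterable[float], b: Sample | Iterable[float]) -> KSResult:
    """Exact two-sample KS distance with miss / false-alarm decomposition.

    The supremum of ``|F1 - F2|`` is scanned over the pooled support of both
    empirical CDFs.  The returned threshold is the midpoint of the leftmost
    maximizing plateau.  Cells above the threshold are classified as coming
    from the higher dose, where "higher dose" is the sample whose empirical
    CDF is *smaller* at the supremum point; ``p_miss`` is the higher-dose
    mass at or below the threshold and ``p_false_alarm`` the lower-dose mass
    above it, so that ``p_miss + p_false_alarm = 1 - ks`` exactly.
    """
    a = a if isinstance(a, Sample) else Sample(a)
    b = b if isinstance(b, Sample) else Sample(b)
    xa = np.sort(a.values)
    xb = np.sort(b.values)
    pooled = np.union1d(xa, xb)
    f1 = np.searchsorted(xa, pooled, side="right") / xa.size
    f2 = np.searchsorted(xb, pooled, side="right") / xb.size
    diff = f1 - f2
    absdiff = np.abs(diff)
    ks = float(absdiff.max())
    imax = int(np.argmax(absdiff))  # leftmost attaining index
    # Threshold: midpoint of the leftmost maximizing interval.  The empirical
    # CDFs are constant on [pooled[imax], pooled[imax + 1]), so any point of
    # that interval realizes the same decomposition.
    if imax + 1 < pooled.size:
        threshold = 0.5 * (pooled[imax] + pooled[imax + 1])
    else:
        threshold = float(pooled[imax])
    # Orientation: the sample with the larger CDF at the supremum plays the
    # role of the lower dose.
    if diff[imax] >= 0:
        f_low, f_high = float(f1[imax]), float(f2[imax])
    else:
        f_low, f_high = float(f2[imax]), float(f1[imax])
    p_miss = f_high  # higher-dose mass not exceeding the threshold
    p_false_alarm = 1.0 - f_low  # lower-dose mass above the threshold
    return KSResult(
        ks=ks,
        threshold=float(threshold),
        p_miss=p_miss,
        p_false_alarm=p_false_alarm,
        p_error=0.5 * (1.0 - ks),
    )


def error_probability(ks: float) -> float:
    """Equal-prior error probability ``(1 - KS)/2`` of the optimal decision."""
    if not 0.0 <= ks <= 1.0:
        raise ValueError("ks must lie in [0, 1]")
    return 0.5 * (1.0 - ks)


def ks_from_error_rates(p_miss: float, p_false_alarm: float) -> float:
    """KS distance implied by miss and false-alarm probabilities."""
    if not (0.0 <= p_miss <= 1.0 and 0.0 <= p_false_alarm <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_miss + p_false_alarm > 1.0 + 1e-12:
        raise ValueError("p_miss + p_false_alarm must not exceed 1")
    return 1.0 - p_miss - p_false_alarm


def gaussian_ks_closed_form(dmu: float, sigma: float) -> float:
    """KS distance between two equal-variance Gaussians with mean gap ``dmu``.

    Equals ``erf(dmu / (2 sqrt(2) sigma))``; for small gaps the distance per
    unit standardized shift approaches ``1/sqrt(2 pi) ~ 0.398``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if dmu < 0:
        raise ValueError("dmu must be non-negative")
    return float(erf(dmu / (2.0 * math.sqrt(2.0) * sigma)))


def discernibility_profile(panel: DosePanel, log_scale: bool = True) -> DiscernibilityProfile:
    """Adjacent-dose discernibility C(d) = KS/Δd and sensitivity S(d) = Δmean/Δd.

    With ``log_scale`` the dose spacing is the natural-log increment
    ``ln(d1) - ln(d)``; pairs whose lower dose is zero then carry NaN for
    C and S (the KS distance is still reported).
    """
    if panel.n_doses < 2:
        raise ValueError("need at least 2 doses")
    pairs, kss, cs, ss = [], [], [], []
    for i in range(panel.n_doses - 1):
        d, d1 = panel.doses[i], panel.doses[i + 1]
        ks = ks_distance(panel.samples[i], panel.samples[i + 1]).ks
        dmean = float(np.mean(panel.samples[i + 1].values) - np.mean(panel.samples[i].values))
        if log_scale:
            if d <= 0:
                dd = np.nan
            else:
                dd = math.log(d1) - math.log(d)
        else:
            dd = d1 - d
        pairs.append((d, d1))
        kss.append(ks)
        cs.append(ks / dd if np.isfinite(dd) else np.nan)
        ss.append(dmean / dd if np.isfinite(dd) else np.nan)
    return DiscernibilityProfile(
        dose_pairs=tuple(pairs),
        ks_values=np.asarray(kss),
        c_values=np.asarray(cs),
        s_values=np.asarray(ss),
    )


def ks_matrix(panel: DosePanel) -> pd.DataFrame:
    """Long-format pairwise KS table over all dose pairs of a panel."""
    rows = []
    for i in range(panel.n_doses):
        for j in range(i + 1, panel.n_doses):
            rows.append(
                {
                    "dose_low": panel.doses[i],
                    "dose_high": panel.doses[j],
                    "ks": ks_distance(panel.samples[i], panel.samples[j]).ks,
                    "adjacent": j == i + 1,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kNN entropy machinery
# ---------------------------------------------------------------------------


def _knn_dist_sorted(xs: np.ndarray, k: int) -> np.ndarray:
    """Distance to the k-th nearest neighbour for each point of a sorted 1-D sample.

    In one dimension the k nearest neighbours of a point lie within the k
    adjacent positions on either side of the sorted array, so no tree is
    needed.
    """
    n = xs.size
    if n <= k:
        raise ValueError("sample size must exceed k")
    cand = np.empty((n, 2 * k))
    for j in range(1, k + 1):
        left = np.empty(n)
        left[:j] = np.inf
        left[j:] = xs[j:] - xs[:-j]
        right = np.empty(n)
        right[-j:] = np.inf
        right[:-j] = xs[j:] - xs[:-j]
        cand[:, j - 1] = left
        cand[:, k + j - 1] = right
    return np.partition(cand, k - 1, axis=1)[:, k - 1]


def _kl_entropy_sorted(xs: np.ndarray, k: int) -> float:
    """Kozachenko-Leonenko differential entropy (nats) of a sorted 1-D sample."""
    n = xs.size
    eps = _knn_dist_sorted(xs, k)
    eps = np.maximum(eps, 1e-300)
    return float(digamma(n) - digamma(k) + math.log(2.0) + np.mean(np.log(eps)))


def _jittered_sorted_samples(panel: DosePanel, seed: int) -> list[np.ndarray]:
    """Sorted per-dose values with deterministic tie-breaking jitter.

    A uniform jitter of relative magnitude ``JITTER_REL`` (relative to the
    pooled readout scale) is added so that exact ties, common for discrete
    molecule counts, do not collapse nearest-neighbour distances to zero.
    MI is invariant under this perturbation to within estimator tolerance.
    """
    rng = np.random.default_rng(seed)
    scale = max(float(np.max(np.abs(np.concatenate([s.values for s in panel.samples])))), 1.0)
    out = []
    for s in panel.samples:
        jit = rng.uniform(-1.0, 1.0, s.values.size) * JITTER_REL * scale
        out.append(np.sort(s.values + jit))
    return out


def _mixture_counts(priors: np.ndarray, sizes: np.ndarray, k: int) -> np.ndarray:
    """Per-dose draw counts for a stratified without-replacement mixture sample.

    The mixture size is the largest N for which ``p_i * N <= n_i`` for every
    dose with positive prior mass, capped at the pooled size; counts are
    apportioned by the largest-remainder rule.  Doses whose apportioned count
    would not support a k-th same-dose neighbour (count <= k) are dropped
    from the mixture.
    """
    total = int(sizes.sum())
    pos = priors > 0
    caps = np.floor(sizes[pos] / priors[pos])
    n_mix = int(min(total, caps.min()))
    n_mix = max(n_mix, 2)
    exact = priors * n_mix
    base = np.minimum(np.floor(exact).astype(np.intp), sizes.astype(np.intp))
    remainder = n_mix - int(base.sum())
    if remainder > 0:
        frac = exact - np.floor(exact)
        frac[base >= sizes] = -1.0  # cannot take more than available
        order = np.argsort(-frac, kind="stable")
        for idx in order[:remainder]:
            base[idx] += 1
    base[base <= k] = 0
    return base


class _KnnMI:
    """Radius-sharing kNN MI estimator for a discrete dose and scalar readout.

    Discrete-conditional adaptation of the Kraskov machinery: for every point
    of a prior-weighted mixture sample, the distance to its k-th nearest
    neighbour *within the same dose* defines a radius, and the number of
    mixture points of any dose strictly inside that radius enters the digamma
    estimate

        MI = psi(N) + psi(k) - <psi(n_dose)> - <psi(m)>   (nats).

    Sharing the radius between the conditional and the marginal term cancels
    the density-dependent bias of plain entropy differences.  Arbitrary
    priors are handled by assembling the mixture from seeded nested random
    subsets of the per-dose samples (without replacement, so subsets remain
    i.i.d. draws from their conditionals); with equal priors and equal sample
    sizes the mixture is the full pooled sample and the estimator reduces to
    the standard equal-weight form.
    """

    def __init__(self, panel: DosePanel, k: int, seed: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        if min(panel.n_per_dose) <= k:
            raise ValueError("each dose needs at least k+1 cells")
        self.k = k
        self.sizes = np.asarray(panel.n_per_dose)
        sorted_samples = _jittered_sorted_samples(panel, seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        # nested random subsets: permute once per replicate, prefix-take per
        # evaluation; averaging over replicates smooths the subset-resampling
        # ripple of the objective across priors
        self.n_subset_reps = 4
        self.permuted = [
            [xs[rng.permutation(xs.size)] for xs in sorted_samples]
            for _ in range(self.n_subset_reps)
        ]

    def mi_bits(self, priors: np.ndarray) -> float:
        counts = _mixture_counts(priors, self.sizes, self.k)
        if np.array_equal(counts, self.sizes):
            return self._mi_bits_once(counts, self.permuted[0])
        return float(
            np.mean([self._mi_bits_once(counts, perm) for perm in self.permuted])
        )

    def _mi_bits_once(self, counts: np.ndarray, permuted: list[np.ndarray]) -> float:
        k = self.k
        parts, labels = [], []
        for i, m in enumerate(counts):
            if m > 0:
                parts.append(permuted[i][:m])
                labels.append(np.full(m, i, dtype=np.intp))
        values = np.concatenate(parts)
        labels = np.concatenate(labels)
        n_tot = values.size
        order = np.argsort(values, kind="stable")
        values, labels = values[order], labels[order]
        rho = np.empty(n_tot)
        for i, m in enumerate(counts):
            if m > 0:
                mask = labels == i
                # values is globally sorted, so each same-dose subset is too
                rho[mask] = _knn_dist_sorted(values[mask], k)
        # m_j: mixture points of any dose strictly within rho_j (self included)
        lo = np.searchsorted(values, values - rho, side="right")
        hi = np.searchsorted(values, values + rho, side="left")
        m_all = hi - lo
        n_label = counts[labels]
        mi_nats = (
            digamma(n_tot)
            + digamma(k)
            - float(np.mean(digamma(n_label)))
            - float(np.mean(digamma(np.maximum(m_all, 1))))
        )
        return mi_nats / LN2


def mi_given_priors(
    panel: DosePanel, priors: PriorVector | Sequence[float], k: int = 4, seed: int = 0
) -> MIEstimate:
    """kNN estimate of MI (bits) between dose and readout for given priors.

    Uses the radius-sharing discrete-conditional Kraskov-style estimator (see
    :class:`_KnnMI`): the marginal term is computed on a prior-weighted
    mixture sample assembled by deterministic stratified resampling (without
    replacement) from the per-dose samples, and the same k-th neighbour
    radius is shared between conditional and marginal counts so their biases
    cancel.  Negative estimates (estimator noise near independence) are
    clipped to zero.  Deterministic given ``seed`` (tie-breaking jitter and
    the mixture subsets).
    """
    priors = priors if isinstance(priors, PriorVector) else PriorVector(priors)
    if len(priors) != panel.n_doses:
        raise ValueError("priors length must match number of doses")
    est = _KnnMI(panel, k, seed)
    return MIEstimate(
        mi_bits=max(est.mi_bits(priors.p), 0.0),
        priors=priors,
        k_neighbors=k,
        n_per_dose=panel.n_per_dose,
    )


# ---------------------------------------------------------------------------
# prior maximization (steepest ascent on the simplex)
# ---------------------------------------------------------------------------


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    n = v.size
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, n + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _steepest_ascent(
    objective: Callable[[np.ndarray], float],
    n: int,
    seed: int,
    grad_step: float = 1e-3,
    init_step: float = 0.1,
    tol_bits: float = 1e-4,
    max_iter: int = 500,
    n_restarts: int = 3,
) -> tuple[np.ndarray, float, bool, int]:
    """Maximize a bits-valued objective over the probability simplex.

    Finite-difference gradient (central differences of size ``grad_step`` in
    prior space, the perturbed point being re-projected onto the simplex),
    backtracking line search halving from ``init_step``, convergence when the
    improvement over an iteration drops below ``tol_bits``.  Restarts from
    the uniform prior and ``n_restarts - 1`` random priors.
    """
    rng = np.random.default_rng(seed)
    starts = [np.full(n, 1.0 / n)]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.dirichlet(np.ones(n)))
    best_p, best_f = starts[0], -np.inf
    any_converged = False
    total_iter = 0
    for p0 in starts:
        p = _project_simplex(np.asarray(p0, dtype=float))
        f = objective(p)
        converged = False
        for _ in range(max_iter):
            total_iter += 1
            grad = np.empty(n)
            for i in range(n):
                e = np.zeros(n)
                e[i] = grad_step
                f_plus = objective(_project_simplex(p + e))
                f_minus = objective(_project_simplex(p - e))
                grad[i] = (f_plus - f_minus) / (2.0 * grad_step)
            direction = grad - grad.mean()  # tangent to the simplex
            if not np.any(np.abs(direction) > 0):
                converged = True
                break
            step = init_step
            improved = False
            f_new, p_new = f, p
            for _ in range(25):
                cand = _project_simplex(p + step * direction)
                f_cand = objective(cand)
                if f_cand > f:
                    f_new, p_new, improved = f_cand, cand, True
                    break
                step *= 0.5
            if not improved:
                converged = True
                break
            gain = f_new - f
            p, f = p_new, f_new
            if gain < tol_bits:
                converged = True
                break
        any_converged = any_converged or converged
        if f > best_f:
            best_p, best_f = p, f
    return best_p, best_f, any_converged, total_iter


def maximize_mi(panel: DosePanel, k: int = 4, seed: int = 0, **ascent_kwargs) -> MIEstimate:
    """Prior-maximized kNN mutual information (channel-capacity estimate).

    Maximizes :func:`mi_given_priors` over the input prior with a
    steepest-ascent method on the simplex.  On non-convergence the best
    iterate is returned with ``converged=False``.
    """
    est = _KnnMI(panel, k, seed)

    def objective(p: np.ndarray) -> float:
        return est.mi_bits(p)

    p_best, f_best, converged, n_iter = _steepest_ascent(
        objective, panel.n_doses, seed=seed, **ascent_kwargs
    )
    return MIEstimate(
        mi_bits=max(f_best, 0.0),
        priors=PriorVector(p_best / p_best.sum()),
        k_neighbors=k,
        n_per_dose=panel.n_per_dose,
        converged=converged,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# Blahut-Arimoto oracle on kNN conditional densities
# ---------------------------------------------------------------------------


def _knn_density_at(xs: np.ndarray, query: np.ndarray, k: int, own: bool) -> np.ndarray:
    """kNN density estimate of the sample ``xs`` (sorted) at query points.

    ``own=True`` marks queries that are the sample's own points, for which the
    k-th neighbour excludes the point itself.
    """
    n = xs.size
    if own:
        eps = _knn_dist_sorted(xs, k)
    else:
        pos = np.searchsorted(xs, query)
        cand = np.empty((query.size, 2 * k))
        for j in range(1, k + 1):
            li = np.clip(pos - j, 0, n - 1)
            ri = np.clip(pos + j - 1, 0, n - 1)
            cand[:, j - 1] = np.where(pos - j >= 0, np.abs(query - xs[li]), np.inf)
            cand[:, k + j - 1] = np.where(pos + j - 1 < n, np.abs(xs[ri] - query), np.inf)
        eps = np.partition(cand, k - 1, axis=1)[:, k - 1]
    eps = np.maximum(eps, 1e-300)
    return k / (n * 2.0 * eps)


def blahut_arimoto_mi(
    panel: DosePanel,
    k: int = 4,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 5000,
) -> MIEstimate:
    """Capacity-achieving prior by Blahut-Arimoto on kNN conditional densities.

    Serves as an independent optimization route against the steepest-ascent
    of :func:`maximize_mi`: the channel is represented by plug-in kNN density
    estimates of each conditional readout distribution evaluated at every
    sample point, and the classical Blahut-Arimoto fixed point iteration is
    run on that representation.  The reported ``mi_bits`` is the plug-in MI
    at the final prior; for like-for-like value comparisons evaluate
    :func:`mi_given_priors` at the returned prior.
    """
    nd = panel.n_doses
    sorted_samples = _jittered_sorted_samples(panel, seed)
    # dens[i][j] = list over doses j of f_i evaluated at the points of dose j
    dens = [[None] * nd for _ in range(nd)]
    for i in range(nd):
        for j in range(nd):
            dens[i][j] = _knn_density_at(
                sorted_samples[i], sorted_samples[j], k, own=(i == j)
            )
    p = np.full(nd, 1.0 / nd)
    mi_nats = 0.0
    for _ in range(max_iter):
        # D_i = E_{x ~ f_i} log(f_i(x) / f_p(x)), Monte Carlo over sample i
        d = np.empty(nd)
        for i in range(nd):
            f_mix = np.zeros_like(dens[i][i])
            for j in range(nd):
                f_mix += p[j] * dens[j][i]
            d[i] = float(np.mean(np.log(dens[i][i] / np.maximum(f_mix, 1e-300))))
        w = p * np.exp(d - d.max())
        p_new = w / w.sum()
        mi_new = float(np.dot(p_new, d))
        if abs(mi_new - mi_nats) < tol and np.max(np.abs(p_new - p)) < 1e-9:
            p = p_new
            mi_nats = mi_new
            break
        p, mi_nats = p_new, mi_new
    return MIEstimate(
        mi_bits=max(mi_nats / LN2, 0.0),
        priors=PriorVector(p),
        k_neighbors=k,
        n_per_dose=panel.n_per_dose,
    )


# ---------------------------------------------------------------------------
# Gaussian oracles
# ---------------------------------------------------------------------------


def gaussian_mi_quadrature(
    spec: GaussianSpec, priors: PriorVector | Sequence[float]
) -> float:
    """MI (bits) of a discrete-input Gaussian-output channel by quadrature.

    Deterministic adaptive integration of each conditional term
    ``p_i \\int f_i log2(f_i / f)`` over ``mean_i ± 10 max(sd)`` with absolute
    tolerance 1e-9 per term.
    """
    priors = priors if isinstance(priors, PriorVector) else PriorVector(priors)
    if len(priors) != spec.n_components:
        raise ValueError("priors length must match number of components")
    mus, sds, p = spec.means, spec.sds, priors.p
    span = 10.0 * float(sds.max())
    inv_norm = 1.0 / (sds * math.sqrt(2.0 * math.pi))
    inv_2var = 0.5 / sds**2

    def _pdf(x, j):
        return inv_norm[j] * math.exp(-((x - mus[j]) ** 2) * inv_2var[j])

    active = [int(j) for j in np.nonzero(p > 0)[0]]

    def make_integrand(i):
        def integrand(x):
            fi = _pdf(x, i)
            if fi <= 0:
                return 0.0
            f = 0.0
            for j in active:
                f += p[j] * _pdf(x, j)
            return fi * math.log2(fi / f)

        return integrand

    total = 0.0
    for i in range(spec.n_components):
        if p[i] == 0:
            continue
        val, err = integrate.quad(
            make_integrand(i),
            mus[i] - span,
            mus[i] + span,
            epsabs=1e-9,
            limit=400,
        )
        if not np.isfinite(val) or err > 1e-6:
            raise RuntimeError("quadrature failed to converge")
        total += p[i] * val
    return max(total, 0.0)


def maximize_mi_gaussian(spec: GaussianSpec, seed: int = 0, **ascent_kwargs) -> MIEstimate:
    """Prior-maximized quadrature MI for Gaussian conditionals (oracle truth)."""

    def objective(p: np.ndarray) -> float:
        return gaussian_mi_quadrature(spec, PriorVector(p / p.sum()))

    p_best, f_best, converged, n_iter = _steepest_ascent(
        objective, spec.n_components, seed=seed, **ascent_kwargs
    )
    return MIEstimate(
        mi_bits=max(f_best, 0.0),
        priors=PriorVector(p_best / p_best.sum()),
        k_neighbors=0,
        n_per_dose=(),
        converged=converged,
        n_iterations=n_iter,
    )


def validate_estimator(
    spec: GaussianSpec,
    n_per_dose: Sequence[int],
    k: int = 4,
    n_reps: int = 20,
    seed: int = 0,
) -> dict:
    """Relative inaccuracy of the sample-based capacity estimate vs quadrature.

    Draws ``n_reps`` panels from the Gaussian spec (one seeded substream per
    replicate), maximizes the kNN MI on each, and compares with the
    prior-maximized quadrature MI of the same spec.  Returns a summary with
    the per-replicate relative errors.
    """
    n_per_dose = np.asarray(n_per_dose, dtype=int)
    if n_per_dose.size != spec.n_components:
        raise ValueError("n_per_dose length must match spec components")
    if np.any(n_per_dose <= k):
        raise ValueError("sample sizes must exceed k")
    truth = maximize_mi_gaussian(spec, seed=seed).mi_bits
    root = np.random.SeedSequence(seed)
    rel_errors = []
    estimates = []
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        samples = [
            rng.normal(mu, sd, size=n)
            for mu, sd, n in zip(spec.means, spec.sds, n_per_dose)
        ]
        panel = DosePanel(np.arange(1, spec.n_components + 1), samples)
        est = maximize_mi(panel, k=k, seed=int(child.generate_state(1)[0] % 2**31))
        estimates.append(est.mi_bits)
        rel_errors.append(abs(est.mi_bits - truth) / truth)
    rel_errors = np.asarray(rel_errors)
    return {
        "truth_bits": truth,
        "estimates_bits": np.asarray(estimates),
        "rel_errors": rel_errors,
        "mean_rel_error": float(rel_errors.mean()),
        "max_rel_error": float(rel_errors.max()),
        "n_reps": n_reps,
        "k": k,
    }


# ---------------------------------------------------------------------------
# sqrt(MI) ~ KS proportionality
# ---------------------------------------------------------------------------


def sqrt_mi_ks_correlation(panel: DosePanel, k: int = 4, seed: int = 0) -> float:
    """Pearson r between pairwise sqrt(maximized MI) and KS over all dose pairs."""
    if panel.n_doses < 3:
        raise ValueError("need at least 3 doses")
    sqrt_mi, kss = [], []
    for i in range(panel.n_doses):
        for j in range(i + 1, panel.n_doses):
            sub = panel.subset([i, j])
            sqrt_mi.append(math.sqrt(maximize_mi(sub, k=k, seed=seed).mi_bits))
            kss.append(ks_distance(panel.samples[i], panel.samples[j]).ks)
    sqrt_mi = np.asarray(sqrt_mi)
    kss = np.asarray(kss)
    if np.ptp(sqrt_mi) == 0 or np.ptp(kss) == 0:
        raise ValueError("degenerate (zero-variance) vectors; correlation undefined")
    return float(stats.pearsonr(sqrt_mi, kss)[0])
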
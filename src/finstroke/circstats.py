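"""Circular statistics for event timings on the stroke circle.

Event timings (muscle onsets/offsets, kinematic extrema) live on the
0-360 deg stroke circle, with the start of propulsion at 0 deg and the
start of recovery at 180 deg.  This module provides the descriptive
summaries (mean direction, mean resultant length, angular variance and
standard error) and the four-test decision tree used to analyse them:

1. Kuiper goodness of fit against a maximum-likelihood von Mises fit
   decides whether the sample is von Mises.
2. Uniformity is then tested with Rayleigh's test (von Mises samples)
   or the Hermans-Rasson test (everything else).
3. Two samples are compared only when both are non-uniform, with the
   Watson-Williams F test when both are von Mises with mean resultant
   length above a cutoff (default 0.45), and the non-parametric
   two-sample Watson U^2 test otherwise.

All angles are degrees in [0, 360) unless a function says otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "AngleSample",
    "CircularSummary",
    "CircTestResult",
    "circ_summary",
    "vonmises_mle",
    "kuiper_statistic",
    "kuiper_vonmises",
    "rayleigh",
    "hermans_rasson_statistic",
    "hermans_rasson",
    "watson_williams",
    "watson_u2",
    "timing_decision_tree",
]


@dataclass(frozen=True)
class AngleSample:
    """A set of event timings on the stroke circle, in degrees [0, 360)."""

    angles: np.ndarray
    label: tuple = ("", "", "")

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 1:
            raise ValueError("angles must be one-dimensional")
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        if np.any((a < 0) | (a >= 360)):
            raise ValueError("angles must lie in [0, 360)")
        object.__setattr__(self, "angles", a)

    @property
    def n(self) -> int:
        return self.angles.size

    @property
    def radians(self) -> np.ndarray:
        return np.deg2rad(self.angles)


@dataclass(frozen=True)
class CircularSummary:
    """Descriptive circular statistics of one angle sample.

    ``ang_var`` is the unit-free angular variance 1 - R_bar; ``ang_dev_deg``
    is the angular deviation sqrt(2 (1 - R_bar)) converted to degrees, the
    convention used when results are printed as "mean +/- variance" in
    degrees.  ``ang_sem_deg`` is the large-sample circular standard error of
    the mean direction.
    """

    mean_deg: float
    R_bar: float
    ang_var: float
    ang_dev_deg: float
    ang_sem_deg: float
    n: int
    mean_defined: bool = True


@dataclass(frozen=True)
class CircTestResult:
    test: str
    statistic: float
    p: float
    df: tuple | None = None
    selection_trace: str = ""
    extra: dict = field(default_factory=dict)


def _as_sample(x) -> AngleSample:
    if isinstance(x, AngleSample):
        return x
    return AngleSample(np.asarray(x, dtype=float) % 360.0)


def _resultant(rad: np.ndarray) -> tuple[float, float]:
    """Mean direction (rad) and mean resultant length of angles in radians."""
    C = np.cos(rad).mean()
    S = np.sin(rad).mean()
    return float(np.arctan2(S, C)), float(np.hypot(C, S))


def circ_summary(sample) -> CircularSummary:
    """Mean direction, resultant length, angular variance/deviation and s.e.m."""
    sample = _as_sample(sample)
    if sample.n == 0:
        raise ValueError("empty angle sample")
    rad = sample.radians
    mu, rbar = _resultant(rad)
    mean_deg = float(np.rad2deg(mu) % 360.0)
    ang_var = 1.0 - rbar
    ang_dev = float(np.rad2deg(np.sqrt(max(2.0 * ang_var, 0.0))))
    mean_defined = rbar > 1e-12
    if not mean_defined:
        warnings.warn("mean resultant length ~ 0: mean direction undefined")
        mean_deg = float("nan")
    # Large-sample circular standard error (Fisher 1993, eq. 4.21):
    # se = sqrt((1 - alpha2) / (2 n Rbar^2)) with alpha2 the second
    # trigonometric moment about the mean direction.
    if mean_defined and sample.n > 1:
        alpha2 = float(np.cos(2.0 * (rad - mu)).mean())
        var_hat = max(1.0 - alpha2, 0.0) / (2.0 * sample.n * rbar**2)
        sem = float(np.rad2deg(np.sqrt(var_hat)))
    else:
        sem = float("nan")
    return CircularSummary(
        mean_deg=mean_deg,
        R_bar=rbar,
        ang_var=ang_var,
        ang_dev_deg=ang_dev,
        ang_sem_deg=sem,
        n=sample.n,
        mean_defined=mean_defined,
    )


# --- von Mises fit -----------------------------------------------------------


def _a1inv(rbar: float) -> float:
    """Invert A1(kappa) = I1/I0: Best & Fisher approximation."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def vonmises_mle(sample) -> tuple[float, float]:
    """Maximum-likelihood (mu_deg, kappa) of a von Mises fit."""
    sample = _as_sample(sample)
    mu, rbar = _resultant(sample.radians)
    if rbar >= 1.0 - 1e-12:
        raise ValueError("degenerate sample: all angles identical, kappa -> inf")
    return float(np.rad2deg(mu) % 360.0), _a1inv(rbar)


def kuiper_statistic(u: np.ndarray) -> float:
    """Kuiper V statistic of values in [0, 1] against the uniform law."""
    u = np.sort(np.asarray(u, dtype=float))
    n = u.size
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    return float(d_plus + d_minus)


def kuiper_vonmises(sample, n_boot: int = 500, seed: int | None = None) -> CircTestResult:
    """Kuiper goodness-of-fit test of a von Mises distribution.

    Parameters are fitted by maximum likelihood, the sample is transformed
    through the fitted CDF, and the Kuiper V statistic is referred to a
    parametric-bootstrap null (parameters refitted within each replicate,
    accounting for estimation).  Small p rejects the von Mises model.
    """
    sample = _as_sample(sample)
    if sample.n < 5:
        raise ValueError("Kuiper von Mises test needs n >= 5")
    try:
        mu, kappa = vonmises_mle(sample)
    except ValueError:
        return CircTestResult(
            test="kuiper_vm", statistic=float("inf"), p=0.0,
            selection_trace="degenerate sample: von Mises fit undefined",
        )
    mu_rad = np.deg2rad(mu)
    v_obs = kuiper_statistic(sps.vonmises.cdf(sample.radians, kappa, loc=mu_rad))
    rng = np.random.default_rng(seed)
    v_null = np.empty(n_boot)
    for b in range(n_boot):
        sim = sps.vonmises.rvs(kappa, loc=mu_rad, size=sample.n, random_state=rng)
        m_b, r_b = _resultant(sim)
        k_b = _a1inv(min(r_b, 1 - 1e-12))
        v_null[b] = kuiper_statistic(sps.vonmises.cdf(sim, k_b, loc=m_b))
    p = float((np.sum(v_null >= v_obs) + 1) / (n_boot + 1))
    return CircTestResult(
        test="kuiper_vm", statistic=v_obs, p=p,
        extra={"mu_deg": mu, "kappa": kappa, "n_boot": n_boot},
    )


# --- uniformity --------------------------------------------------------------


def rayleigh(sample) -> CircTestResult:
    """Rayleigh test of circular uniformity against a unimodal alternative.

    z = n * R_bar^2, with the standard asymptotic p-value series.
    """
    sample = _as_sample(sample)
    n = sample.n
    if n < 3:
        raise ValueError("Rayleigh test needs n >= 3")
    _, rbar = _resultant(sample.radians)
    R = n * rbar
    z = n * rbar**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    return CircTestResult(test="rayleigh", statistic=float(z), p=float(min(max(p, 0.0), 1.0)))


def hermans_rasson_statistic(rad: np.ndarray) -> float:
    """Hermans-Rasson uniformity statistic (Landler-Ruxton-Malkemper form)."""
    d = rad[:, None] - rad[None, :]
    t = np.abs(np.abs(d) - np.pi) - np.pi / 2
    t -= 2.895 * (np.abs(np.sin(d)) - 2 / np.pi)
    return float(t.sum() / rad.size)


def hermans_rasson(sample, n_boot: int = 10_000, seed: int | None = None) -> CircTestResult:
    """Hermans-Rasson uniformity test with a Monte-Carlo null.

    More powerful than Rayleigh against multimodal (e.g. axially bimodal)
    departures from uniformity; the null is simulated by uniform resampling
    at the observed n.
    """
    sample = _as_sample(sample)
    n = sample.n
    if n < 3:
        raise ValueError("Hermans-Rasson test needs n >= 3")
    t_obs = hermans_rasson_statistic(sample.radians)
    rng = np.random.default_rng(seed)
    t_null = hermans_rasson_null(n, n_boot, rng)
    p = float((np.sum(t_null >= t_obs) + 1) / (n_boot + 1))
    return CircTestResult(test="hermans_rasson", statistic=t_obs, p=p,
                          extra={"n_boot": n_boot})


def hermans_rasson_null(n: int, n_reps: int, rng: np.random.Generator,
                        batch: int = 256) -> np.ndarray:
    """Simulated null distribution of the Hermans-Rasson statistic at size n."""
    out = np.empty(n_reps)
    done = 0
    while done < n_reps:
        m = min(batch, n_reps - done)
        theta = rng.uniform(0, 2 * np.pi, size=(m, n))
        d = theta[:, :, None] - theta[:, None, :]
        t = np.abs(np.abs(d) - np.pi) - np.pi / 2
        t -= 2.895 * (np.abs(np.sin(d)) - 2 / np.pi)
        out[done:done + m] = t.sum(axis=(1, 2)) / n
        done += m
    return out


# --- two-sample tests --------------------------------------------------------


def watson_williams(a, b) -> CircTestResult:
    """Watson-Williams F test for equal mean directions of two samples.

    Assumes both samples are von Mises with a common, reasonably large
    concentration; a warning is emitted when the pooled R_bar falls below
    the range where the correction factor is trusted (< 0.45).
    """
    a, b = _as_sample(a), _as_sample(b)
    if a.n < 3 or b.n < 3:
        raise ValueError("Watson-Williams needs n >= 3 per sample")
    n1, n2 = a.n, b.n
    N = n1 + n2
    _, r1 = _resultant(a.radians)
    _, r2 = _resultant(b.radians)
    R1, R2 = n1 * r1, n2 * r2
    _, r_all = _resultant(np.concatenate([a.radians, b.radians]))
    R = N * r_all
    rw = (R1 + R2) / N
    if rw < 0.45:
        warnings.warn(
            "Watson-Williams: pooled mean resultant length < 0.45; "
            "concentration assumption doubtful"
        )
    kappa = _a1inv(min(rw, 1 - 1e-12))
    correction = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    denom = N - R1 - R2
    if denom <= 0:
        F = 0.0 if R1 + R2 - R <= 1e-12 else float("inf")
    else:
        F = correction * (N - 2) * max(R1 + R2 - R, 0.0) / denom
    p = float(sps.f.sf(F, 1, N - 2)) if np.isfinite(F) else 0.0
    return CircTestResult(test="watson_williams", statistic=float(F), p=p,
                          df=(1, N - 2))


def _watson_u2_stat(a_rad: np.ndarray, b_rad: np.ndarray) -> float:
    n, m = a_rad.size, b_rad.size
    N = n + m
    pooled = np.concatenate([a_rad, b_rad])
    order = np.argsort(pooled, kind="mergesort")
    in_a = (order < n).astype(float)
    f1 = np.cumsum(in_a) / n
    f2 = np.cumsum(1.0 - in_a) / m
    d = f1 - f2
    return float(n * m / N**2 * (np.sum(d**2) - np.sum(d) ** 2 / N))

def watson_u2(a, b, method: str = "auto", n_perm: int = 5000,
              seed: int | None = None) -> CircTestResult:
    """Two-sample Watson U^2 test for a common circular distribution.

    Rotation invariant and distribution free.  p-value from the asymptotic
    series when both samples have n >= 8 (``method="auto"``), otherwise by
    permutation of the pooled sample.
    """
    a, b = _as_sample(a), _as_sample(b)
    u2 = _watson_u2_stat(a.radians, b.radians)
    use_perm = method == "permutation" or (method == "auto" and min(a.n, b.n) < 8)
    if use_perm:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a.radians, b.radians])
        cnt = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _watson_u2_stat(perm[: a.n], perm[a.n:]) >= u2 - 1e-15:
                cnt += 1
        p = (cnt + 1) / (n_perm + 1)
        method_used = "permutation"
    else:
        # Asymptotic tail: P(U^2 > u) = 2 sum_{k>=1} (-1)^{k-1} exp(-2 k^2 pi^2 u)
        k = np.arange(1, 51)
        p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2))
        p = float(min(max(p, 0.0), 1.0))
        method_used = "asymptotic"
    return CircTestResult(test="watson_u2", statistic=u2, p=float(p),
                          extra={"method": method_used})


# --- decision tree -----------------------------------------------------------


def timing_decision_tree(
    a,
    b=None,
    alpha: float = 0.05,
    rbar_cutoff: float = 0.45,
    kuiper_boot: int = 500,
    hr_boot: int = 10_000,
    seed: int | None = None,
) -> list[CircTestResult]:
    """Run the full circular decision tree on one or two angle samples.

    Per sample: Kuiper test of a von Mises fit decides between Rayleigh
    (von Mises) and Hermans-Rasson (not) for uniformity.  When a second
    sample is given, the mean directions are compared only if both samples
    are non-uniform, with Watson-Williams iff both are von Mises and both
    mean resultant lengths exceed ``rbar_cutoff``, else Watson U^2.  Every
    result carries a ``selection_trace`` explaining the branch taken.
    """
    rng = np.random.default_rng(seed)
    samples = [_as_sample(a)] + ([_as_sample(b)] if b is not None else [])
    results: list[CircTestResult] = []
    is_vm: list[bool] = []
    non_uniform: list[bool] = []
    rbars: list[float] = []

    for i, s in enumerate(samples):
        tag = f"sample{i + 1}"
        kp = kuiper_vonmises(s, n_boot=kuiper_boot,
                             seed=int(rng.integers(2**31)))
        vm = kp.p >= alpha
        is_vm.append(vm)
        results.append(CircTestResult(
            test=kp.test, statistic=kp.statistic, p=kp.p, df=kp.df,
            selection_trace=f"{tag}: von Mises {'retained' if vm else 'rejected'}"
                            f" (Kuiper p={kp.p:.3g})",
            extra=kp.extra,
        ))
        if vm:
            un = rayleigh(s)
            trace = f"{tag}: von Mises -> Rayleigh uniformity"
        else:
            un = hermans_rasson(s, n_boot=hr_boot, seed=int(rng.integers(2**31)))
            trace = f"{tag}: not von Mises -> Hermans-Rasson uniformity"
        nu = un.p < alpha
        non_uniform.append(nu)
        rbars.append(circ_summary(s).R_bar)
        results.append(CircTestResult(
            test=un.test, statistic=un.statistic, p=un.p, df=un.df,
            selection_trace=trace + f"; {'non-uniform' if nu else 'uniform'}"
                                    f" (p={un.p:.3g})",
            extra=un.extra,
        ))

    if b is not None:
        if not all(non_uniform):
            results.append(CircTestResult(
                test="none", statistic=float("nan"), p=float("nan"),
                selection_trace="two-sample comparison skipped: at least one "
                                "sample uniform (no consistent timing)",
            ))
        elif all(is_vm) and all(r > rbar_cutoff for r in rbars):
            ww = watson_williams(samples[0], samples[1])
            results.append(CircTestResult(
                test=ww.test, statistic=ww.statistic, p=ww.p, df=ww.df,
                selection_trace="both von Mises with R_bar > "
                                f"{rbar_cutoff} -> Watson-Williams",
            ))
        else:
            wu = watson_u2(samples[0], samples[1],
                           seed=int(rng.integers(2**31)))
            results.append(CircTestResult(
                test=wu.test, statistic=wu.statistic, p=wu.p, df=wu.df,
                selection_trace="von Mises or concentration condition failed "
                                "-> Watson U2",
                extra=wu.extra,
            ))
    return results
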
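"""Trace processing: corrections, quality gates and two-level idealization.

Raw per-molecule channel traces are turned into accepted, idealized binary
binding records via the standard corrections for this kind of recording:

1. cross-talk subtraction (10 % of the donor channel leaks into I_AD),
2. baseline correction against the post-bleach level,
3. acceptor bleach-step counting on I_AA (single step required: one
   acceptor, hence one receptor, per waveguide),
4. two-level hidden-Markov idealization of the corrected I_AD up to the
   bleach, and
5. rejection of molecules with signal-to-noise ratio below 2, where S/N is
   the idealized amplitude over the RMS noise of the unbound time points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy import stats
from scipy.optimize import curve_fit

from zmwbind.simulate import TraceSet

SNR_THRESHOLD = 2.0
DEFAULT_CROSSTALK = 0.10

# hmmlearn's ConvergenceMonitor logs benign sub-tolerance oscillations
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)


@dataclass
class IdealizedTrace:
    """Binary bound/unbound record for one molecule, with QC metadata."""

    molecule_id: str
    states: np.ndarray | None  # 0 unbound / 1 bound, up to analysis end
    amplitude: float
    snr: float
    bleach_frame: int | None
    n_bleach_steps: int
    accepted: bool
    reason: str = ""
    concentration: float = 0.0
    frame_period: float = 0.1
    corrected: np.ndarray | None = None  # the corrected intensity window


# ---------------------------------------------------------------------------
# corrections


def crosstalk_correct(i_ad: np.ndarray, i_dd: np.ndarray, alpha: float = DEFAULT_CROSSTALK) -> np.ndarray:
    """Subtract donor cross-talk: returns ``I_AD - alpha * I_DD``."""
    i_ad = np.asarray(i_ad, dtype=float)
    i_dd = np.asarray(i_dd, dtype=float)
    if i_ad.shape != i_dd.shape:
        raise ValueError("I_AD and I_DD must have equal length")
    if not (0 <= alpha < 1):
        raise ValueError("alpha must be in [0, 1)")
    return i_ad - alpha * i_dd


def baseline_correct(
    i: np.ndarray,
    bleach_frame: int,
    slow_decay: bool = False,
    frame_period: float = 0.1,
    min_tau: float = 50.0,
) -> np.ndarray:
    """Zero the baseline using the post-bleach segment.

    The mean intensity after the acceptor bleach is subtracted.  With
    ``slow_decay``, a very slow single-exponential drift (time constant
    >= ``min_tau`` seconds) is additionally fitted to the unbound-level
    points (lower half of the intensity distribution) and removed.
    """
    i = np.asarray(i, dtype=float)
    n = len(i)
    if not (0 <= bleach_frame < n):
        raise ValueError("bleach_frame outside sequence")
    if n - bleach_frame < 10:
        raise ValueError("need at least 10 post-bleach frames for baseline estimation")
    out = i - i[bleach_frame:].mean()
    if slow_decay:
        from scipy.optimize import least_squares

        t = np.arange(n) * frame_period
        # robust fit tracks the unbound baseline; binding events are upward
        # outliers that the soft-L1 loss discounts
        sigma = 1.4826 * np.median(np.abs(np.diff(out))) / np.sqrt(2)
        f_scale = max(float(sigma), 1e-6)

        def resid(p):
            a, log_tau, c = p
            return out - (a * np.exp(-t / np.exp(log_tau)) + c)

        p0 = (max(out[: n // 10].mean() - out[bleach_frame:].mean(), 1e-6),
              np.log(100.0), 0.0)
        res = least_squares(
            resid, p0, loss="soft_l1", f_scale=f_scale,
            bounds=([-np.inf, np.log(min_tau), -np.inf],
                    [np.inf, np.log(1e4), np.inf]),
        )
        if res.success:
            a, log_tau, _ = res.x
            out = out - a * np.exp(-t / np.exp(log_tau))
            out = out - out[bleach_frame:].mean()
        else:
            warnings.warn("slow-decay fit did not converge; mean subtraction only")
    return out


# ---------------------------------------------------------------------------
# bleach-step detection


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best single change-point by least squares; returns (index, sse)."""
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)
    left_sse = csq[k - 1] - csum[k - 1] ** 2 / k
    rtot = csum[-1] - csum[k - 1]
    rsq = csq[-1] - csq[k - 1]
    right_sse = rsq - rtot**2 / (n - k)
    sse = left_sse + right_sse
    j = int(np.argmin(sse))
    return int(k[j]), float(sse[j])


def detect_bleach_steps(
    i_aa: np.ndarray, min_size: int = 5, penalty: float | None = None
) -> tuple[int, int | None]:
    """Count downward intensity steps in I_AA by change-point segmentation.

    Penalized least-squares binary segmentation: a split is accepted when it
    lowers ``n * log(SSE / n)`` by more than the BIC-style penalty
    (default ``3 * log(n)``).  Returns ``(n_down_steps, bleach_frame)``
    where ``bleach_frame`` is the index of the last downward step (or None
    when no step is found; such molecules are rejected downstream).
    """
    x = np.asarray(i_aa, dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 frames")
    if penalty is None:
        penalty = 3.0 * np.log(n)

    breakpoints: list[int] = []

    def cost(seg: np.ndarray) -> float:
        sse = float(np.sum((seg - seg.mean()) ** 2))
        return len(seg) * np.log(max(sse, 1e-300) / len(seg))

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if hi - lo < 2 * min_size:
            return
        k, _ = _best_split(seg)
        if k < min_size or (hi - lo) - k < min_size:
            # re-search restricted to admissible interior points
            interior = slice(min_size, hi - lo - min_size + 1)
            nloc = hi - lo
            csum = np.cumsum(seg)
            csq = np.cumsum(seg * seg)
            ks = np.arange(1, nloc)[interior.start - 1 : interior.stop - 1]
            if len(ks) == 0:
                return
            l_sse = csq[ks - 1] - csum[ks - 1] ** 2 / ks
            rtot = csum[-1] - csum[ks - 1]
            rsq = csq[-1] - csq[ks - 1]
            r_sse = rsq - rtot**2 / (nloc - ks)
            j = int(np.argmin(l_sse + r_sse))
            k = int(ks[j])
        full = cost(seg)
        split = cost(seg[:k]) + cost(seg[k:])
        if full - split > penalty:
            breakpoints.append(lo + k)
            recurse(lo, lo + k)
            recurse(lo + k, hi)

    recurse(0, n)
    breakpoints.sort()
    down = []
    edges = [0] + breakpoints + [n]
    for bi, bp in enumerate(breakpoints):
        left = x[edges[bi] : bp]
        right = x[bp : edges[bi + 2]]
        if right.mean() < left.mean():
            down.append(bp)
    if not down:
        return 0, None
    return len(down), down[-1]


# ---------------------------------------------------------------------------
# idealization


def idealize_two_level(
    i: np.ndarray,
    n_starts: int = 4,
    seed: int = 0,
    molecule_id: str = "mol0",
    concentration: float = 0.0,
    frame_period: float = 0.1,
    bleach_frame: int | None = None,
    n_bleach_steps: int = 1,
) -> IdealizedTrace:
    """Two-state Gaussian-emission HMM idealization of a corrected trace.

    EM with multi-start (fixed seeds plus a percentile-based deterministic
    initialization), most-probable state path by Viterbi decoding.  The
    amplitude is the difference of the two level means; if the fitted levels
    are indistinguishable (amplitude below the unbound RMS noise) the
    idealization is empty and the molecule is rejected.
    """
    x = np.asarray(i, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 frames to idealize")
    X = x.reshape(-1, 1)

    def _make(rs, init_means=None):
        hmm = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=200,
            tol=1e-6,
            random_state=rs,
            init_params="stc" if init_means is not None else "stmc",
            min_covar=1e-6,
        )
        if init_means is not None:
            hmm.means_ = np.asarray(init_means).reshape(2, 1)
        return hmm

    candidates = []
    lo, hi = np.percentile(x, [10, 90])
    if hi - lo < 1e-12:
        hi = lo + 1e-12
    inits = [(0, (lo, hi))] + [(seed + 1 + k, None) for k in range(n_starts - 1)]
    for rs, means in inits:
        hmm = _make(rs, means)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                hmm.fit(X)
                candidates.append((hmm.score(X), rs, hmm))
            except (ValueError, np.linalg.LinAlgError):
                continue
    if not candidates:
        return IdealizedTrace(molecule_id, None, 0.0, 0.0, bleach_frame,
                              n_bleach_steps, False, "idealization_failed",
                              concentration, frame_period)
    candidates.sort(key=lambda t: (-t[0], t[1]))
    best = candidates[0][2]

    # a single-level description must lose by BIC, else there is no second
    # level to speak of (guards against splitting pure noise into two levels)
    n = len(x)
    ll1 = float(np.sum(stats.norm.logpdf(x, x.mean(), max(x.std(), 1e-12))))
    ll2 = float(best.score(X))
    bic1 = 2 * np.log(n) - 2 * ll1  # 2 params: mean, variance
    bic2 = 7 * np.log(n) - 2 * ll2  # 2 means, 2 variances, 3 chain params
    if bic2 >= bic1:
        return IdealizedTrace(molecule_id, None, 0.0, 0.0, bleach_frame,
                              n_bleach_steps, False, "levels_indistinguishable",
                              concentration, frame_period)

    path = best.predict(X)
    means = best.means_.ravel()
    hi_state = int(np.argmax(means))
    states = (path == hi_state).astype(np.int8)
    amplitude = float(abs(means[hi_state] - means[1 - hi_state]))

    unbound = x[states == 0]
    if len(unbound) < 2 or states.all() or not states.any():
        return IdealizedTrace(molecule_id, None, amplitude, 0.0, bleach_frame,
                              n_bleach_steps, False, "no_events",
                              concentration, frame_period)
    rms = float(np.sqrt(np.mean((unbound - means[1 - hi_state]) ** 2)))
    snr = amplitude / rms if rms > 0 else np.inf
    if amplitude < rms:
        return IdealizedTrace(molecule_id, None, amplitude, snr, bleach_frame,
                              n_bleach_steps, False, "levels_indistinguishable",
                              concentration, frame_period)
    return IdealizedTrace(molecule_id, states, amplitude, snr, bleach_frame,
                          n_bleach_steps, True, "", concentration, frame_period)


# ---------------------------------------------------------------------------
# pipeline wrapper and S/N distribution


def process_trace(
    ts: TraceSet,
    alpha: float = DEFAULT_CROSSTALK,
    snr_threshold: float = SNR_THRESHOLD,
    seed: int = 0,
    slow_decay: bool = False,
    donor_only: bool = False,
) -> IdealizedTrace:
    """Full per-molecule processing: bleach gate, corrections, idealization.

    With ``donor_only`` the post-bleach I_DD segment is idealized instead of
    the pre-bleach smFRET segment (binding read out from ligand fluorescence
    alone, valid at low concentrations).
    Acceptance requires exactly one acceptor bleach step, a non-empty
    idealization and S/N >= ``snr_threshold`` (rejection is strict <).
    """
    n_steps, bleach = detect_bleach_steps(ts.I_AA)
    if n_steps != 1:
        return IdealizedTrace(ts.molecule_id, None, 0.0, 0.0, bleach, n_steps,
                              False, f"bleach_steps={n_steps}", ts.concentration,
                              ts.frame_period)
    corrected = crosstalk_correct(ts.I_AD, ts.I_DD, alpha)
    try:
        corrected = baseline_correct(corrected, bleach, slow_decay=slow_decay,
                                     frame_period=ts.frame_period)
    except ValueError as exc:
        return IdealizedTrace(ts.molecule_id, None, 0.0, 0.0, bleach, n_steps,
                              False, str(exc), ts.concentration, ts.frame_period)
    window = ts.I_DD[bleach:] if donor_only else corrected[:bleach]
    try:
        ideal = idealize_two_level(
            window, seed=seed, molecule_id=ts.molecule_id,
            concentration=ts.concentration, frame_period=ts.frame_period,
            bleach_frame=bleach, n_bleach_steps=n_steps,
        )
    except ValueError as exc:
        return IdealizedTrace(ts.molecule_id, None, 0.0, 0.0, bleach, n_steps,
                              False, str(exc), ts.concentration, ts.frame_period)
    if ideal.accepted and not passes_snr_gate(ideal.snr, snr_threshold):
        ideal.accepted = False
        ideal.reason = f"snr<{snr_threshold:g}"
    ideal.corrected = np.asarray(window, dtype=float)
    return ideal


def passes_snr_gate(snr: float, threshold: float = SNR_THRESHOLD) -> bool:
    """Quality gate on signal-to-noise: rejection is strict (S/N < threshold
    rejected), so a molecule at exactly the threshold is kept."""
    return not (snr < threshold)


@dataclass
class SnrDistribution:
    shape: float
    scale: float
    n: int
    fraction_below_threshold: float
    threshold: float


def fit_snr_distribution(snrs, threshold: float = SNR_THRESHOLD) -> SnrDistribution:
    """Maximum-likelihood gamma fit of the cohort S/N distribution."""
    x = np.asarray(list(snrs), dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 S/N values")
    if np.any(x <= 0):
        raise ValueError("S/N values must be positive")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    frac = float(np.mean(x < threshold))
    return SnrDistribution(float(shape), float(scale), len(x), frac, threshold)
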
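"""Dwell-time statistics: censor-aware exponential mixtures, binding curves
and per-molecule heterogeneity diagnostics.

Dwells are the uninterrupted sojourns of an idealized binary trace in the
bound or unbound class.  Two censoring rules apply before any fitting:

* the first and last event of every molecule are edge events (truncated by
  the recording window or the acceptor bleach) and are excluded;
* events shorter than the dead time (default 200 ms, i.e. two frames at
  10 Hz) are unresolvable and excluded; fitted densities are accordingly
  left-truncated, i.e. conditioned on ``duration > dead_time``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit, minimize
from sklearn.mixture import GaussianMixture

from zmwbind.process import IdealizedTrace

DEAD_TIME = 0.2  # s
FRAME_PERIOD = 0.1  # s

UNBOUND, BOUND = "unbound", "bound"


# ---------------------------------------------------------------------------
# dwell extraction


def _runs(states: np.ndarray):
    """Run-length encode a binary sequence into (value, length) pairs."""
    states = np.asarray(states)
    if len(states) == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, len(states)]
    return [(int(states[s]), int(e - s)) for s, e in zip(starts, ends)]


def extract_dwells(
    idealized: list[IdealizedTrace],
    dead_time: float = DEAD_TIME,
    frame_period: float | None = None,
) -> pd.DataFrame:
    """Run-length encode accepted idealizations into a dwell table.

    Returns all raw dwells with ``edge_flag`` (first/last event per
    molecule) and ``subthreshold_flag`` (duration < dead_time).  Use
    :func:`analysis_view` for the censored view used by every fit.
    """
    rows = []
    for it in idealized:
        if not it.accepted or it.states is None:
            continue
        fp = frame_period if frame_period is not None else it.frame_period
        runs = _runs(it.states)
        n = len(runs)
        for ei, (val, length) in enumerate(runs):
            dur = length * fp
            rows.append(
                {
                    "molecule_id": it.molecule_id,
                    "concentration_M": it.concentration,
                    "state_class": BOUND if val else UNBOUND,
                    "duration_s": dur,
                    "event_index": ei,
                    "edge_flag": ei == 0 or ei == n - 1,
                    "subthreshold_flag": dur < dead_time - 1e-12,
                }
            )
    cols = ["molecule_id", "concentration_M", "state_class", "duration_s",
            "event_index", "edge_flag", "subthreshold_flag"]
    return pd.DataFrame(rows, columns=cols)


def analysis_view(dwells: pd.DataFrame) -> pd.DataFrame:
    """Censored dwell view: edge and sub-dead-time events removed."""
    return dwells[~dwells["edge_flag"] & ~dwells["subthreshold_flag"]].copy()


# ---------------------------------------------------------------------------
# exponential mixture MLE with left truncation


@dataclass
class ExpMixtureFit:
    """Maximum-likelihood exponential mixture, left-truncated at dead time.

    ``taus`` sorted ascending with aligned ``amplitudes`` (untruncated
    mixture weights, summing to 1).  ``reduced`` flags a degenerate collapse
    (two indistinguishable components or a vanishing amplitude).
    """

    k: int
    taus: np.ndarray
    amplitudes: np.ndarray
    log_likelihood: float
    dead_time: float
    n: int
    converged: bool = True
    reduced: bool = False
    ci: dict = field(default_factory=dict)

    def density(self, t: np.ndarray) -> np.ndarray:
        """Truncated mixture density on (dead_time, inf)."""
        t = np.asarray(t, dtype=float)
        z = np.sum(self.amplitudes * np.exp(-self.dead_time / self.taus))
        f = np.zeros_like(t)
        for a, tau in zip(self.amplitudes, self.taus):
            f += a * np.exp(-t / tau) / tau
        return np.where(t > self.dead_time, f / z, 0.0)


def _em_exp_mixture(s: np.ndarray, taus0, w0, max_iter=2000, tol=1e-10):
    """EM for a k-component exponential mixture on shifted data s >= 0."""
    taus = np.array(taus0, dtype=float)
    w = np.array(w0, dtype=float)
    w /= w.sum()
    n = len(s)
    prev = -np.inf
    for _ in range(max_iter):
        # E step
        logp = np.log(w)[None, :] - np.log(taus)[None, :] - s[:, None] / taus[None, :]
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        ll = float(np.sum(m.ravel() + np.log(tot.ravel())))
        r = p / tot
        # M step
        nk = r.sum(axis=0)
        w = nk / n
        taus = (r * s[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        # frame quantization puts an atom at s = 0; floor tau well below the
        # frame period so a component cannot degenerate onto it
        taus = np.maximum(taus, 1e-3)
        if abs(ll - prev) < tol * (1 + abs(ll)):
            return taus, w, ll, True
        prev = ll
    return taus, w, ll, False


def _mixture_loglik(s: np.ndarray, taus, w, quantization: float | None = None) -> float:
    taus = np.asarray(taus, dtype=float)
    w = np.asarray(w, dtype=float)
    if quantization:
        # binned (interval) likelihood: P(s = m*dt) = (1 - q) q^m, q = e^(-dt/tau)
        logq = -quantization / taus
        log1mq = np.log1p(-np.exp(logq))
        m_cnt = np.round(s / quantization)
        logp = np.log(w)[None, :] + log1mq[None, :] + m_cnt[:, None] * logq[None, :]
    else:
        logp = np.log(w)[None, :] - np.log(taus)[None, :] - s[:, None] / taus[None, :]
    m = logp.max(axis=1, keepdims=True)
    return float(np.sum(m.ravel() + np.log(np.exp(logp - m).sum(axis=1))))


def _em_geometric_mixture(m_cnt: np.ndarray, dt: float, taus0, w0,
                          max_iter=2000, tol=1e-10):
    """EM for a mixture of geometrics on frame counts m >= 0 (the binned
    form of an exponential mixture quantized to multiples of dt)."""
    taus = np.maximum(np.array(taus0, dtype=float), 1e-3)
    w = np.array(w0, dtype=float)
    w /= w.sum()
    n = len(m_cnt)
    prev = -np.inf
    for _ in range(max_iter):
        logq = -dt / taus
        log1mq = np.log1p(-np.exp(logq))
        logp = np.log(np.maximum(w, 1e-300))[None, :] + log1mq[None, :] \
            + m_cnt[:, None] * logq[None, :]
        mx = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - mx)
        tot = p.sum(axis=1, keepdims=True)
        ll = float(np.sum(mx.ravel() + np.log(tot.ravel())))
        r = p / tot
        nk = r.sum(axis=0)
        w = nk / n
        mean_m = (r * m_cnt[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        q = np.clip(mean_m / (1.0 + mean_m), 1e-12, 1 - 1e-12)
        taus = np.maximum(-dt / np.log(q), 1e-3)
        if abs(ll - prev) < tol * (1 + abs(ll)):
            return taus, w, ll, True
        prev = ll
    return taus, w, ll, False


def fit_exp_mixture(
    dwells,
    k: int,
    dead_time: float = DEAD_TIME,
    n_starts: int = 8,
    seed: int = 0,
    compute_ci: bool = False,
    quantization: float | None = None,
) -> ExpMixtureFit:
    """ML fit of a k-exponential mixture conditioned on duration > dead_time.

    The truncated mixture in ``t`` is equivalent to an untruncated mixture
    in ``s = t - dead_time`` with reweighted components; EM is run on ``s``
    with multi-start and fixed seeds, and the untruncated amplitudes are
    recovered afterwards.  95 % profile-likelihood confidence intervals are
    computed on request.

    With ``quantization`` set to the frame period, the likelihood is the
    binned (interval-censored) one: durations are integer frame counts, so
    ``s`` follows a mixture of geometrics with ``q_i = exp(-dt/tau_i)``.
    Use this for frame-quantized dwell tables: the continuous density is
    degenerate on the atom of dwells exactly at the dead time, which a
    spurious sub-frame component can otherwise latch onto.
    """
    t = np.asarray(list(dwells), dtype=float)
    n = len(t)
    if n < 10:
        raise ValueError("need at least 10 dwells")
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if k > n / 5:
        raise ValueError(f"k={k} too large for n={n} dwells")
    if np.any(t <= dead_time - 1e-12):
        raise ValueError("all dwells must exceed the dead time")
    s = np.maximum(t - dead_time, 0.0)

    # truncation point of the untruncated-duration scale: with binning, a
    # recorded t covers true durations from t - dt/2
    trunc = dead_time - 0.5 * quantization if quantization else dead_time

    if k == 1:
        if quantization:
            m_mean = float(np.mean(np.round(s / quantization)))
            q = m_mean / (1.0 + m_mean)
            tau = float(-quantization / np.log(max(q, 1e-300))) if q > 0 else 1e-3
        else:
            tau = float(s.mean())  # closed-form shifted-exponential MLE
        ll = _mixture_loglik(s, [tau], [1.0], quantization)
        fit = ExpMixtureFit(1, np.array([tau]), np.array([1.0]), ll, dead_time, n)
    else:
        rng = np.random.default_rng(seed)
        qs = np.quantile(s, np.linspace(0.15, 0.9, k))
        best = None
        for start in range(n_starts):
            jitter = rng.uniform(0.3, 3.0, k) if start else np.ones(k)
            taus0 = np.maximum(qs * jitter, 1e-6)
            w0 = rng.dirichlet(np.ones(k)) if start else np.full(k, 1.0 / k)
            if quantization:
                m_cnt = np.round(s / quantization)
                taus, w, ll, conv = _em_geometric_mixture(
                    m_cnt, quantization, taus0, w0)
            else:
                taus, w, ll, conv = _em_exp_mixture(s, taus0, w0)
            if best is None or ll > best[2] + 1e-12:
                best = (taus, w, ll, conv)
        taus, w, ll, conv = best
        order = np.argsort(taus)
        taus, w = taus[order], w[order]
        # recover untruncated amplitudes (w_i = a_i exp(-trunc/tau_i) / Z),
        # in log space to survive tau << dead_time degeneracies
        log_a = np.log(np.maximum(w, 1e-300)) + trunc / taus
        log_a -= log_a.max()
        a = np.exp(log_a)
        a /= a.sum()
        reduced = bool(
            np.min(w) < 1e-3
            or np.any(np.diff(taus) / taus[1:] < 0.01)
            or np.min(taus) < dead_time / 2
        )
        fit = ExpMixtureFit(k, taus, a, ll, dead_time, n, converged=conv, reduced=reduced)

    if compute_ci:
        fit.ci = _profile_cis(s, fit, quantization=quantization)
    return fit


def _pack(taus, w):
    x = list(np.log(taus))
    if len(w) > 1:
        x += list(np.log(w[:-1] / w[-1]))
    return np.array(x)


def _unpack(x, k):
    taus = np.exp(x[:k])
    if k == 1:
        return taus, np.array([1.0])
    z = np.r_[x[k:], 0.0]
    w = np.exp(z - z.max())
    return taus, w / w.sum()


def _profile_cis(s: np.ndarray, fit: ExpMixtureFit, level: float = 0.95,
                 quantization: float | None = None) -> dict:
    """Profile-likelihood CIs for each tau (and truncated weight) by grid scan."""
    k = fit.k
    crit = stats.chi2.ppf(level, 1) / 2.0
    z = np.sum(fit.amplitudes * np.exp(-fit.dead_time / fit.taus))
    w = fit.amplitudes * np.exp(-fit.dead_time / fit.taus) / z
    ll_max = fit.log_likelihood
    cis = {}

    def profile(fix_idx, fix_val):
        if k == 1:
            return _mixture_loglik(s, [fix_val], [1.0], quantization)
        free = [i for i in range(k) if i != fix_idx]

        def nll(x):
            taus_f = np.exp(x[: k - 1])
            taus = np.empty(k)
            taus[fix_idx] = fix_val
            taus[free] = taus_f
            zz = np.r_[x[k - 1 :], 0.0]
            ww = np.exp(zz - zz.max())
            ww = ww / ww.sum()
            return -_mixture_loglik(s, taus, ww, quantization)

        x0 = np.r_[np.log(fit.taus[free]), np.log(w[:-1] / w[-1])]
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 3000})
        return -res.fun

    for i in range(k):
        tau_hat = fit.taus[i]
        grid = tau_hat * np.geomspace(0.4, 2.5, 41)
        dev = np.array([ll_max - profile(i, g) for g in grid])
        inside = dev <= crit
        if inside.any():
            lo = grid[inside][0]
            hi = grid[inside][-1]
        else:  # pathological; report point estimate
            lo = hi = tau_hat
        cis[f"tau{i+1}"] = (float(lo), float(hi))
    return cis


def lr_component_test(fit_k: ExpMixtureFit, fit_k1: ExpMixtureFit) -> float:
    """Likelihood-ratio p-value for k vs k+1 components, chi^2 with 2 df."""
    if fit_k1.k != fit_k.k + 1:
        raise ValueError("second fit must have exactly one more component")
    if fit_k.n != fit_k1.n or fit_k.dead_time != fit_k1.dead_time:
        raise ValueError("fits must be on identical data")
    d = 2.0 * (fit_k1.log_likelihood - fit_k.log_likelihood)
    if d < -1e-6 * max(1.0, abs(fit_k.log_likelihood)):
        raise RuntimeError(
            "larger model has lower likelihood: optimization failure "
            f"(2*dLL = {d:.3g})"
        )
    return float(stats.chi2.sf(max(d, 0.0), df=2))


def select_components(
    dwells, dead_time: float = DEAD_TIME, alpha: float = 0.001, seed: int = 0,
    quantization: float | None = FRAME_PERIOD,
) -> tuple[int, dict[int, ExpMixtureFit]]:
    """Choose the exponential component count by the chi^2(2) LR criterion.

    Starting from one component, a further component is added while the LR
    test rejects at ``alpha`` and the larger fit has not collapsed.  Dwell
    tables from idealized traces are frame-quantized, so the binned
    likelihood is the default here.
    """
    fits = {kk: fit_exp_mixture(dwells, kk, dead_time, seed=seed,
                                quantization=quantization) for kk in (1, 2, 3)}
    k = 1
    while k < 3:
        p = lr_component_test(fits[k], fits[k + 1])
        if p < alpha and not fits[k + 1].reduced:
            k += 1
        else:
            break
    return k, fits


# ---------------------------------------------------------------------------
# binding curve


@dataclass
class BindingCurveFit:
    bmax: float
    kd: float
    concentrations: np.ndarray
    bound_probabilities: np.ndarray
    bmax_fixed: bool = False

    def predict(self, c) -> np.ndarray:
        return self.bmax / (1.0 + self.kd / np.asarray(c, dtype=float))


def bound_probability(
    idealized: list[IdealizedTrace], fix_bmax: bool = False
) -> BindingCurveFit:
    """Fraction of frames bound per concentration, with a saturation fit.

    Fits ``Bmax / (1 + Kd / c)`` by least squares weighted with the frame
    counts per concentration; ``fix_bmax`` pins Bmax = 1 (the form used for
    bulk anisotropy saturation curves).
    """
    per_conc: dict[float, list[int]] = {}
    for it in idealized:
        if not it.accepted or it.states is None:
            continue
        nb, nf = int(it.states.sum()), len(it.states)
        per_conc.setdefault(it.concentration, [0, 0])
        per_conc[it.concentration][0] += nb
        per_conc[it.concentration][1] += nf
    concs = np.array(sorted(per_conc))
    fracs = np.array([per_conc[c][0] / max(per_conc[c][1], 1) for c in concs])
    weights = np.array([per_conc[c][1] for c in concs], dtype=float)
    if len(concs) < 3:
        raise ValueError("need at least 3 concentrations for a binding-curve fit")
    if np.all(fracs == 0):
        raise ValueError("zero bound frames at every concentration")
    sigma = 1.0 / np.sqrt(weights)
    if fix_bmax:
        popt, _ = curve_fit(lambda c, kd: 1.0 / (1.0 + kd / c), concs, fracs,
                            p0=(np.median(concs),), sigma=sigma, maxfev=10000)
        bmax, kd = 1.0, float(popt[0])
    else:
        popt, _ = curve_fit(lambda c, bmax, kd: bmax / (1.0 + kd / c), concs, fracs,
                            p0=(max(fracs.max(), 0.1), np.median(concs)),
                            sigma=sigma, maxfev=10000)
        bmax, kd = float(popt[0]), float(popt[1])
    return BindingCurveFit(bmax, kd, concs, fracs, fix_bmax)


# ---------------------------------------------------------------------------
# heterogeneity diagnostics


@dataclass
class HeterogeneityResult:
    per_molecule: pd.DataFrame
    hist: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    delta_bic: float
    ashman_d: float
    modality: str  # 'unimodal' | 'bimodal' | 'undetermined'
    overlay: dict


def per_molecule_heterogeneity(
    dwells: pd.DataFrame,
    min_events: int = 2,
    n_bins: int = 25,
    mixture_fits: dict[str, ExpMixtureFit] | None = None,
    seed: int = 0,
) -> HeterogeneityResult:
    """Per-molecule mean dwell times, their 2D histogram, and a modality
    diagnostic distinguishing dynamic from static heterogeneity.

    Dynamic heterogeneity (every molecule interconverts among kinetic
    modes) yields a unimodal per-molecule distribution centred between the
    mixture time constants; static subpopulations yield bimodal clustering
    at the population-specific (tau_u, tau_b) pairs.  The diagnostic is the
    BIC difference between 1- and 2-component Gaussian mixtures on the log
    per-molecule mean bound times (positive = bimodal favoured).
    """
    av = analysis_view(dwells)
    rows = []
    for mol, g in av.groupby("molecule_id"):
        if len(g) < min_events:
            continue
        b = g.loc[g.state_class == BOUND, "duration_s"]
        u = g.loc[g.state_class == UNBOUND, "duration_s"]
        if len(b) == 0 or len(u) == 0:
            continue
        rows.append({"molecule_id": mol, "mean_bound_s": b.mean(),
                     "mean_unbound_s": u.mean(), "n_events": len(g)})
    pm = pd.DataFrame(rows, columns=["molecule_id", "mean_bound_s",
                                     "mean_unbound_s", "n_events"])
    if len(pm) == 0:
        raise ValueError("no molecules with enough analysis events")

    lo = min(pm.mean_bound_s.min(), pm.mean_unbound_s.min())
    hi = max(pm.mean_bound_s.max(), pm.mean_unbound_s.max())
    edges = np.geomspace(max(lo * 0.8, 1e-3), hi * 1.2, n_bins + 1)
    H, xe, ye = np.histogram2d(pm.mean_unbound_s, pm.mean_bound_s, bins=[edges, edges])

    logb = np.log10(pm.mean_bound_s.values).reshape(-1, 1)
    if len(pm) >= 4:
        g1 = GaussianMixture(1, random_state=seed).fit(logb)
        g2 = GaussianMixture(2, random_state=seed, n_init=3).fit(logb)
        delta_bic = float(g1.bic(logb) - g2.bic(logb))
        # bimodality requires strong BIC evidence (> 6) AND separated
        # components (Ashman's D > 2): two overlapping Gaussians also
        # out-fit a merely skewed unimodal distribution at large n
        mu = g2.means_.ravel()
        var = g2.covariances_.ravel()
        ashman_d = float(abs(mu[0] - mu[1]) / np.sqrt((var[0] + var[1]) / 2))
        modality = "bimodal" if (delta_bic > 6 and ashman_d > 2) else "unimodal"
    else:
        delta_bic = float("nan")
        ashman_d = float("nan")
        modality = "undetermined"

    overlay = {}
    if mixture_fits:
        for cls, fit in mixture_fits.items():
            overlay[cls] = {
                "taus": fit.taus.tolist(),
                "weighted_average": float(np.sum(fit.amplitudes * fit.taus)),
            }
    return HeterogeneityResult(pm, H, xe, ye, delta_bic, ashman_d, modality, overlay)


def dwell_correlations(
    dwells: pd.DataFrame, order: int = 1, n_boot: int = 200, seed: int = 0
) -> dict[str, dict]:
    """Pearson correlations of log dwell durations between event pairs.

    First order pairs each unbound event i with the following bound event
    i+1; second order pairs successive unbound (i, i+2) and successive
    bound events.  Pairs are built within molecules from strictly adjacent
    analysis events and pooled; CIs are bootstrap percentiles over pairs.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    av = analysis_view(dwells)
    pairings = (
        [("U_i,B_i+1", UNBOUND, BOUND, 1)]
        if order == 1
        else [("U_i,U_i+2", UNBOUND, UNBOUND, 2), ("B_i,B_i+2", BOUND, BOUND, 2)]
    )
    rng = np.random.default_rng(seed)
    out = {}
    for name, cls_a, cls_b, lag in pairings:
        xs, ys = [], []
        for _, g in av.groupby("molecule_id"):
            g = g.sort_values("event_index")
            idx = g.event_index.values
            cls = g.state_class.values
            dur = g.duration_s.values
            pos = {e: j for j, e in enumerate(idx)}
            for j, e in enumerate(idx):
                if cls[j] != cls_a:
                    continue
                j2 = pos.get(e + lag)
                if j2 is None or cls[j2] != cls_b:
                    continue
                xs.append(dur[j])
                ys.append(dur[j2])
        if len(xs) < 10:
            out[name] = None
            continue
        lx, ly = np.log(np.array(xs)), np.log(np.array(ys))
        r = float(np.corrcoef(lx, ly)[0, 1])
        boots = []
        npairs = len(lx)
        for _ in range(n_boot):
            bi = rng.integers(0, npairs, npairs)
            if np.std(lx[bi]) > 0 and np.std(ly[bi]) > 0:
                boots.append(np.corrcoef(lx[bi], ly[bi])[0, 1])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out[name] = {"r": r, "ci": (float(lo), float(hi)), "n_pairs": npairs}
    return out


# ---------------------------------------------------------------------------
# tetramer first-binding-step analysis


def first_step_tetramer_analysis(
    occupancies: list[np.ndarray],
    dead_time: float = DEAD_TIME,
    frame_period: float = FRAME_PERIOD,
    seed: int = 0,
):
    """Dwell analysis of the 0<->1 occupancy transitions of multisite traces.

    Frames with more than one site occupied are flagged; events touching
    them are excluded so the analysis isolates the first binding step.
    Returns the dwell table and (mono, bi) bound-lifetime mixture fits.
    """
    multi_bound = sum(int(np.sum(o >= 2)) for o in occupancies)
    any_bound = sum(int(np.sum(o >= 1)) for o in occupancies)
    if any_bound and multi_bound / any_bound > 0.20:
        raise ValueError(
            "more than 20% of bound frames have multiple occupancy; "
            "use a lower ligand concentration to isolate the first step"
        )
    ideals = []
    for mi, occ in enumerate(occupancies):
        binary = (np.asarray(occ) >= 1).astype(np.int8)
        ideals.append(
            IdealizedTrace(
                molecule_id=f"tet{mi}", states=binary, amplitude=1.0, snr=np.inf,
                bleach_frame=None, n_bleach_steps=1, accepted=True,
                frame_period=frame_period,
            )
        )
    dw = extract_dwells(ideals, dead_time, frame_period)
    # flag events that overlap a multiply-occupied frame
    bad_rows = []
    for mi, occ in enumerate(occupancies):
        occ = np.asarray(occ)
        binary = (occ >= 1).astype(np.int8)
        start = 0
        for ei, (val, length) in enumerate(_runs(binary)):
            if np.any(occ[start : start + length] >= 2):
                bad_rows.append((f"tet{mi}", ei))
            start += length
    if bad_rows:
        bad_idx = dw.set_index(["molecule_id", "event_index"]).index.isin(bad_rows)
        dw = dw[~bad_idx]

    bound = analysis_view(dw)
    bound = bound.loc[bound.state_class == BOUND, "duration_s"]
    fit1 = fit_exp_mixture(bound, 1, dead_time, seed=seed, quantization=frame_period)
    fit2 = fit_exp_mixture(bound, 2, dead_time, seed=seed, quantization=frame_period)
    return dw, fit1, fit2
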
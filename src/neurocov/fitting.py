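"""Parameter fitting and architecture comparison from population moments.

The workflow mirrors how the circuit models are confronted with data:

1. **Moment lines** — ordinary least squares of the population-averaged
   variance ``<C_ii>(s)`` and pairwise covariance ``<C_ij>(s)`` on the
   population-averaged response ``<r>(s)``.  In the recurrent model both
   lines share the intercept/slope ratio ``a + <V_ext>`` (the external-noise
   strength); in the feed-forward model the covariance line is flat; in the
   gain model the covariance grows quadratically.

2. **Parameter estimates** — the recurrent effective-coupling variability
   ``rho`` from the average noise correlation (``rho = 1/c_N - 1``), the
   second moment ``<B^2>`` from the variance-line slope (``slope = N<B^2>``),
   and moment-matched feed-forward parameters ``(<F>, var F, <r_ext>,
   var r_ext)``.  The feed-forward inversion is a reconstruction by moment
   matching (see the methods note).

3. **Gain-offset search** — the best baseline offset ``a`` under the
   gain-fluctuation model, minimising the pair-level residual
   ``sum_s sum_{i != j} (C_ij(s) - V(s) (r_i + a)(r_j + a))^2`` with the
   per-stimulus gain variance profiled out in closed form.

4. **Architecture comparison** — each architecture is fitted and scored on
   the pair-level covariance structure it predicts, in common relative
   units; the ranked verdict reports the numbers, not a bare label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special

from .exceptions import (
    DegenerateAbscissaError,
    InfeasibleMomentsError,
    TooFewStimuliError,
)
from .ensembles import NetworkEnsembleParams, StimulusEnsembleParams
from .generate import GeneratorConfig, _derive_seeds, generate_dataset
from .popstats import MomentsOrDataset, PopulationSummary, summarize


def folded_normal_mean(mu: float, sigma: float) -> float:
    """``E|X|`` for ``X ~ Normal(mu, sigma^2)``; the mean input variance when
    ``V_ext = |r_ext|`` with normally distributed drives."""
    if sigma == 0:
        return abs(mu)
    z = mu / (sigma * np.sqrt(2.0))
    return float(
        sigma * np.sqrt(2.0 / np.pi) * np.exp(-(z**2)) + mu * special.erf(z)
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> dict:
    """Unweighted OLS line with slope t-statistic; non-finite pairs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ (y - y.mean()) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    rss = float(resid @ resid)
    tss = float((y - y.mean()) @ (y - y.mean()))
    se = np.sqrt(rss / max(n - 2, 1) / sxx) if n > 2 else np.nan
    return {
        "slope": slope,
        "intercept": intercept,
        "ratio": intercept / slope if slope != 0 else np.inf,
        "t_slope": slope / se if se and se > 0 else np.nan,
        "r_squared": 1.0 - rss / tss if tss > 0 else np.nan,
    }


def fit_moment_lines(curve: pd.DataFrame) -> dict:
    """OLS lines of ``<C_ii>`` and ``<C_ij>`` against ``<r>`` across stimuli.

    Returns ``variance_line`` and ``covariance_line`` dicts with slope,
    intercept and intercept/slope ratio.
    """
    x = curve["mean_rate"].to_numpy(dtype=float)
    if np.unique(np.round(x, 12)).size < 3:
        raise TooFewStimuliError("need >= 3 stimuli with distinct <r> for line fits")
    if np.ptp(x) <= 1e-12 * max(np.abs(x).max(), 1.0):
        raise DegenerateAbscissaError("<r> is constant across stimuli")
    return {
        "variance_line": _ols_line(x, curve["mean_var"].to_numpy(dtype=float)),
        "covariance_line": _ols_line(x, curve["mean_cov"].to_numpy(dtype=float)),
    }


def estimate_recurrent_params(
    summary: PopulationSummary,
    lines: dict,
    n: Optional[int] = None,
) -> dict:
    """Invert the recurrent-model predictions for the ensemble parameters.

    ``rho = 1/c_N - 1`` (from the average noise correlation),
    ``<B^2> = slope/N`` (variance line), ``<B>^2 = <B^2>/(1 + rho)`` and
    ``a + <V_ext> = intercept/slope``.
    """
    n = n or summary.n_neurons
    c_n = summary.c_N
    if not 0 < c_n <= 1:
        raise InfeasibleMomentsError(f"average noise correlation c_N={c_n:.4f} outside (0, 1]")
    slope = lines["variance_line"]["slope"]
    if slope <= 0:
        raise InfeasibleMomentsError(f"variance-line slope {slope:.4g} must be positive")
    rho = 1.0 / c_n - 1.0
    second_moment = slope / n
    mean_sq = second_moment / (1.0 + rho)
    return {
        "rho": rho,
        "mean_B": float(np.sqrt(mean_sq)),
        "var_B": rho * mean_sq,
        "second_moment_B": second_moment,
        "v_ext_plus_a": lines["variance_line"]["ratio"],
    }


def _c_in_from_signal_correlation(c_s: float, rho: float, n: int) -> float:
    """Invert ``c_S = (1 + (N-1) c_in) / (1 + rho + (N-1) c_in)`` for c_in."""
    if not 0 < c_s < 1:
        return 0.0
    c_in = (c_s * (1.0 + rho) - 1.0) / ((n - 1) * (1.0 - c_s))
    return float(np.clip(c_in, 0.0, 0.999))


def fit_feedforward_params(summary: PopulationSummary, n: Optional[int] = None) -> dict:
    """Moment-matched feed-forward parameters ``(rho, rho_ext, <F>, var F, <r_ext>)``.

    Matching relations (drives normal, ``V_ext = |r_ext|``, offset taken as
    zero for the baseline-relative data):

    * ``<C_ii> - <r> = N <F^2> <V_ext>`` and ``<C_ij> = N <F>^2 <V_ext>``
      give ``rho = (<C_ii> - <r>) / <C_ij> - 1``.
    * ``mean_s <r>(s) = N <F> <r_ext>``.
    * ``var_s <r>(s) = <F>^2 [(1 - c_in)(N + rho) + c_in N^2] var(r_ext)``
      with ``c_in`` inverted from the average signal correlation.
    * ``<V_ext>`` is the folded-normal mean of the drive distribution, which
      pins down the overall scale ``<F>``.

    Raises
    ------
    InfeasibleMomentsError
        When the implied ``var F`` is negative or the mean covariance is not
        positive (reported rather than clipped).
    """
    n = n or summary.n_neurons
    curve = summary.curve
    x = curve["mean_rate"].to_numpy(dtype=float)
    m1 = float(x.mean())
    s1sq = float(x.var())
    mean_var = float(curve["mean_var"].mean())
    mean_cov = float(curve["mean_cov"].mean())
    if mean_cov <= 0:
        raise InfeasibleMomentsError(
            f"mean pairwise covariance {mean_cov:.4g} <= 0: no shared-input solution"
        )
    rho = (mean_var - m1) / mean_cov - 1.0
    if rho < 0:
        raise InfeasibleMomentsError(
            f"implied var(F) < 0 (rho = {rho:.4f}): variances too small "
            "relative to covariances for a shared-input model"
        )
    if m1 == 0:
        raise InfeasibleMomentsError("mean population response is zero")
    c_in = _c_in_from_signal_correlation(summary.c_S, rho, n)
    q = (1.0 - c_in) * (n + rho) + c_in * n**2
    s_e = float(np.sqrt(s1sq / q))  # = <F> * sd(r_ext)
    scaled_v = folded_normal_mean(m1 / n, s_e)  # = <F> * <V_ext>
    if scaled_v <= 0:
        raise InfeasibleMomentsError("degenerate drive distribution")
    mean_f = (mean_cov / n) / scaled_v
    if mean_f <= 0:
        raise InfeasibleMomentsError(f"implied <F> = {mean_f:.4g} not positive")
    mean_rext = m1 / (n * mean_f)
    var_rext = (s_e / mean_f) ** 2
    return {
        "rho": rho,
        "rho_ext": var_rext / mean_rext**2,
        "mean_F": mean_f,
        "var_F": rho * mean_f**2,
        "mean_rext": mean_rext,
        "var_rext": var_rext,
        "c_in": c_in,
        "mean_v_ext": scaled_v / mean_f,
        "reconstruction": True,  # moment-matching reconstruction of the fit
    }


def _gain_terms(moments, a: float) -> tuple[float, float, float]:
    """Pooled off-diagonal sums for the gain model at offset ``a``.

    Returns ``(sum C^2, sum C*P, sum P^2)`` over all stimuli and i != j,
    with ``P = (r + a)(r + a)^T``.
    """
    c2 = cp = p2 = 0.0
    for m in moments:
        u = m.rates + a
        cu = m.cov @ u
        diag = np.diag(m.cov)
        c2 += float((m.cov**2).sum() - (diag**2).sum())
        cp += float(u @ cu - diag @ u**2)
        u2 = u**2
        p2 += float(u2.sum() ** 2 - (u2**2).sum())
    return c2, cp, p2


def fit_gain_offset(summary: PopulationSummary) -> dict:
    """Best baseline offset under the gain-fluctuation model.

    For each candidate offset ``a`` the per-stimulus gain variance
    ``V(s) = sum_{i!=j} C_ij u_i u_j / sum_{i!=j} (u_i u_j)^2`` (``u = r + a``)
    is the closed-form least-squares coefficient; a bounded 1-D minimisation
    over ``a in [-max|r|, 10 max|r|]`` then minimises the summed residual.
    Reports the per-stimulus profile, the pooled scalar ``V_ext`` and the
    residual relative to the off-diagonal power.
    """
    moments = summary.moments
    rmax = max(float(np.abs(m.rates).max()) for m in moments)
    rmax = max(rmax, 1e-6)

    def objective(a: float) -> float:
        resid = 0.0
        for m in moments:
            u = m.rates + a
            diag = np.diag(m.cov)
            num = float(u @ (m.cov @ u) - diag @ u**2)
            u2 = u**2
            den = float(u2.sum() ** 2 - (u2**2).sum())
            c2 = float((m.cov**2).sum() - (diag**2).sum())
            resid += c2 - (num**2 / den if den > 0 else 0.0)
        return resid

    res = optimize.minimize_scalar(
        objective, bounds=(-rmax, 10.0 * rmax), method="bounded",
        options={"xatol": 1e-6 * rmax},
    )
    a_hat = float(res.x)
    v_per_stim = []
    for m in moments:
        u = m.rates + a_hat
        diag = np.diag(m.cov)
        num = float(u @ (m.cov @ u) - diag @ u**2)
        u2 = u**2
        den = float(u2.sum() ** 2 - (u2**2).sum())
        v_per_stim.append(num / den if den > 0 else 0.0)
    c2, cp, p2 = _gain_terms(moments, a_hat)
    v_pooled = cp / p2 if p2 > 0 else 0.0
    residual = float(res.fun)
    return {
        "offset_a": a_hat,
        "v_ext_per_stimulus": np.asarray(v_per_stim),
        "v_ext_pooled": float(v_pooled),
        "residual": residual,
        "rel_residual": residual / c2 if c2 > 0 else np.nan,
        "pooled_rel_residual": (c2 - 2 * v_pooled * cp + v_pooled**2 * p2) / c2
        if c2 > 0
        else np.nan,
    }


@dataclass
class FitReport:
    """Moment-line fits and per-architecture parameter estimates."""

    lines: dict
    data_summary: dict
    recurrent: Optional[dict] = None
    feedforward: Optional[dict] = None
    gain: Optional[dict] = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return clean(
            {
                "lines": self.lines,
                "data_summary": self.data_summary,
                "recurrent": self.recurrent,
                "feedforward": self.feedforward,
                "gain": self.gain,
                "notes": self.notes,
            }
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def fit_population(data: MomentsOrDataset) -> FitReport:
    """Run the full fitting workflow on a dataset or list of moment sets."""
    summary = summarize(data)
    curve = summary.curve
    lines = fit_moment_lines(curve)
    x = curve["mean_rate"].to_numpy(dtype=float)
    report = FitReport(
        lines=lines,
        data_summary={
            "n_neurons": summary.n_neurons,
            "n_stimuli": summary.n_stimuli,
            "c_N": summary.c_N,
            "c_S": summary.c_S,
            "mean_rate": float(x.mean()),
            "var_rate": float(x.var()),
            "mean_var": float(curve["mean_var"].mean()),
            "mean_cov": float(curve["mean_cov"].mean()),
            "ratio_agreement": _ratio_disagreement(lines),
        },
    )
    try:
        report.recurrent = estimate_recurrent_params(summary, lines)
    except InfeasibleMomentsError as err:
        report.notes.append(f"recurrent fit infeasible: {err}")
    try:
        report.feedforward = fit_feedforward_params(summary)
    except InfeasibleMomentsError as err:
        report.notes.append(f"feed-forward fit infeasible: {err}")
    report.gain = fit_gain_offset(summary)
    return report


def _ratio_disagreement(lines: dict) -> float:
    """Normalised disagreement between variance- and covariance-line ratios."""
    rv = lines["variance_line"]["ratio"]
    rc = lines["covariance_line"]["ratio"]
    if not (np.isfinite(rv) and np.isfinite(rc)):
        return 1.0
    denom = abs(rv) + abs(rc)
    return abs(rv - rc) / denom if denom > 0 else 0.0


def generate_surrogate(
    report: FitReport,
    architecture: str,
    n_neurons: int,
    n_stimuli: int,
    n_trials: int,
    seed: int,
):
    """Surrogate dataset with a freshly sampled network matching the fit.

    Builds a :class:`GeneratorConfig` whose ensemble moments reproduce the
    fitted population parameters, then samples a new random network, stimulus
    ensemble and trials.  The gain surrogate takes its rate ensemble from the
    feed-forward moment fit (the gain model leaves average responses free)
    and its covariance parameters from the gain-offset search.
    """
    seeds = _derive_seeds(seed, 2)
    if architecture == "recurrent":
        if report.recurrent is None:
            raise InfeasibleMomentsError("no feasible recurrent fit to generate from")
        p = report.recurrent
        mean_b = p["mean_B"]
        if mean_b <= 0:
            raise InfeasibleMomentsError("fitted <B> not positive")
        ds = report.data_summary
        c_in = _c_in_from_signal_correlation(ds["c_S"], p["rho"], n_neurons)
        q = (1.0 - c_in) * (n_neurons + p["rho"]) + c_in * n_neurons**2
        mean_rext = ds["mean_rate"] / (n_neurons * mean_b)
        var_rext = ds["var_rate"] / (q * mean_b**2)
        offset = p["v_ext_plus_a"] - folded_normal_mean(mean_rext, np.sqrt(var_rext))
        network = NetworkEnsembleParams(
            n=n_neurons, mean_w=mean_b, sd_w=float(np.sqrt(p["var_B"])),
            target="effective_B", seed=seeds[0],
        )
        stimulus = StimulusEnsembleParams(
            n_neurons=n_neurons, n_stimuli=n_stimuli, mean_rext=mean_rext,
            var_rext=var_rext, c_in=c_in, seed=seeds[1],
        )
        config = GeneratorConfig(
            architecture="recurrent", n_neurons=n_neurons, n_stimuli=n_stimuli,
            n_trials=n_trials, offset_a=float(offset), network=network,
            stimulus=stimulus, seed=seed,
        )
    elif architecture == "feedforward":
        if report.feedforward is None:
            raise InfeasibleMomentsError("no feasible feed-forward fit to generate from")
        p = report.feedforward
        network = NetworkEnsembleParams(
            n=n_neurons, mean_w=p["mean_F"], sd_w=float(np.sqrt(p["var_F"])),
            target="feedforward_F", seed=seeds[0],
        )
        stimulus = StimulusEnsembleParams(
            n_neurons=n_neurons, n_stimuli=n_stimuli, mean_rext=p["mean_rext"],
            var_rext=p["var_rext"], c_in=p["c_in"], seed=seeds[1],
        )
        config = GeneratorConfig(
            architecture="feedforward", n_neurons=n_neurons, n_stimuli=n_stimuli,
            n_trials=n_trials, offset_a=0.0, network=network, stimulus=stimulus,
            seed=seed,
        )
    elif architecture == "gain":
        if report.feedforward is None or report.gain is None:
            raise InfeasibleMomentsError(
                "gain surrogate needs a feasible feed-forward rate fit and a gain fit"
            )
        p = report.feedforward
        network = NetworkEnsembleParams(
            n=n_neurons, mean_w=p["mean_F"], sd_w=float(np.sqrt(p["var_F"])),
            target="feedforward_F", seed=seeds[0],
        )
        stimulus = StimulusEnsembleParams(
            n_neurons=n_neurons, n_stimuli=n_stimuli, mean_rext=p["mean_rext"],
            var_rext=p["var_rext"], c_in=p["c_in"], seed=seeds[1],
        )
        config = GeneratorConfig(
            architecture="gain", n_neurons=n_neurons, n_stimuli=n_stimuli,
            n_trials=n_trials, offset_a=float(report.gain["offset_a"]),
            network=network, stimulus=stimulus,
            gain_v_ext=float(max(report.gain["v_ext_pooled"], 0.0)), seed=seed,
        )
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    return generate_dataset(config)


@dataclass
class ArchitectureComparison:
    """Ranked consistency report of the three architectures for one dataset."""

    scores: dict
    ranking: list
    diagnostics: dict
    components: dict

    @property
    def verdict(self) -> str:
        return self.ranking[0]

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return clean(
            {
                "verdict": self.verdict,
                "ranking": self.ranking,
                "scores": self.scores,
                "components": self.components,
                "diagnostics": self.diagnostics,
            }
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def compare_architectures(
    data: MomentsOrDataset,
    min_stimuli: int = 10,
) -> ArchitectureComparison:
    """Score each architecture's consistency with a dataset and rank them.

    Each architecture is fitted and scored on the covariance structure it
    predicts, in common relative units (smaller = more consistent):

    * pair level — predicted off-diagonal covariances ``C_ij(s)``:
      recurrent: per-pair constant times ``(<r>(s) + beta)`` with ``beta``
      the variance-line intercept/slope (the network model ties the
      covariance profile to the population drive); feed-forward: per-pair
      constant times the model-implied input-variance profile (the
      folded-normal mean ``<|r_ext|>(s)`` at the per-stimulus drive level
      implied by the fitted ensemble); gain: pooled
      ``V (r_i + a)(r_j + a)`` from the offset search.
    * curve level — the predicted population-averaged variance ``<C_ii>(s)``
      (feed-forward: slope exactly one in the mean response plus the shared
      input term ``(1 + rho) N <F>^2 <V_ext>(s)``).

    The diagnostics block carries the underlying signatures: the regression
    slopes of the normalised projected variances on ``cos(d, r)``, the
    variance/covariance intercept-slope agreement and the gain-fit residual.
    """
    summary = summarize(data)
    if summary.n_stimuli < min_stimuli:
        raise TooFewStimuliError(
            f"architecture comparison needs >= {min_stimuli} stimuli, "
            f"got {summary.n_stimuli}"
        )
    moments = summary.moments
    curve = summary.curve
    x = curve["mean_rate"].to_numpy(dtype=float)
    v = curve["mean_var"].to_numpy(dtype=float)
    lines = fit_moment_lines(curve)

    n = summary.n_neurons
    n_stim = summary.n_stimuli
    covs = np.stack([m.cov for m in moments])  # (S, N, N)
    off_mask = ~np.eye(n, dtype=bool)
    c_off = covs[:, off_mask]  # (S, N(N-1))
    pair_norm = float((c_off**2).sum())
    curve_norm = float((v**2).sum())

    scores: dict = {}
    components: dict = {}

    # recurrent: C_ij(s) ~ P_ij (<r>(s) + beta_v), variances on the fitted line
    try:
        rec = estimate_recurrent_params(summary, lines)
        beta = rec["v_ext_plus_a"]
        g = x + beta
        p_hat = (c_off * g[:, None]).sum(axis=0) / float(g @ g)
        pair_res = float(((c_off - np.outer(g, p_hat)) ** 2).sum())
        v_hat = lines["variance_line"]["slope"] * x + lines["variance_line"]["intercept"]
        curve_res = float(((v - v_hat) ** 2).sum())
        components["recurrent"] = {"pair": pair_res / pair_norm,
                                   "curve": curve_res / curve_norm}
        scores["recurrent"] = sum(components["recurrent"].values())
    except InfeasibleMomentsError as err:
        rec = None
        components["recurrent"] = {"error": str(err)}
        scores["recurrent"] = np.inf

    # feed-forward: C_ij(s) ~ Q_ij * <V_ext>(s) with the input-variance
    # profile implied by the fitted drive ensemble; variances have unit
    # slope in <r>(s) plus the shared-input term.
    try:
        ff = fit_feedforward_params(summary)
        m_e = x / (n * ff["mean_F"])  # implied per-stimulus mean drive
        sd_within = float(np.sqrt(ff["var_rext"] * (1.0 - ff["c_in"])))
        w = np.array([folded_normal_mean(m, sd_within) for m in m_e])
        wbar = w / w.mean()
        q_hat = (c_off * wbar[:, None]).sum(axis=0) / float(wbar @ wbar)
        pair_res = float(((c_off - np.outer(wbar, q_hat)) ** 2).sum())
        v_hat = x + (1.0 + ff["rho"]) * n * ff["mean_F"] ** 2 * w
        curve_res = float(((v - v_hat) ** 2).sum())
        components["feedforward"] = {"pair": pair_res / pair_norm,
                                     "curve": curve_res / curve_norm}
        scores["feedforward"] = sum(components["feedforward"].values())
    except InfeasibleMomentsError as err:
        ff = None
        components["feedforward"] = {"error": str(err)}
        scores["feedforward"] = np.inf

    # gain: C_ij(s) = V (r_i + a)(r_j + a) with pooled V from the offset search
    gain = fit_gain_offset(summary)
    a_hat = gain["offset_a"]
    v_gain = gain["v_ext_pooled"]
    pair_res = 0.0
    curve_res = 0.0
    for s, m in enumerate(moments):
        u = m.rates + a_hat
        pred = v_gain * np.outer(u, u)
        pair_res += float(((m.cov - pred)[off_mask] ** 2).sum())
        v_hat_s = float(np.mean(u + v_gain * u**2))
        curve_res += (v[s] - v_hat_s) ** 2
    components["gain"] = {"pair": pair_res / pair_norm, "curve": curve_res / curve_norm}
    scores["gain"] = sum(components["gain"].values())

    ranking = sorted(scores, key=lambda k: scores[k])

    mu_line = _ols_line(curve["cos_dr"].to_numpy(dtype=float),
                        curve["sigma_mu2_norm"].to_numpy(dtype=float))
    d_line = _ols_line(curve["cos_dr"].to_numpy(dtype=float),
                       curve["sigma_d2_norm"].to_numpy(dtype=float))
    diagnostics = {
        "sigma_mu_vs_cos": {k: mu_line[k] for k in ("slope", "t_slope")},
        "sigma_d_vs_cos": {k: d_line[k] for k in ("slope", "t_slope")},
        "ratio_variance_line": lines["variance_line"]["ratio"],
        "ratio_covariance_line": lines["covariance_line"]["ratio"],
        "ratio_disagreement": _ratio_disagreement(lines),
        "c_N": summary.c_N,
        "c_S": summary.c_S,
        "gain_offset": a_hat,
        "gain_v_ext": v_gain,
        "gain_rel_residual": gain["rel_residual"],
        "n_stimuli": n_stim,
        "n_neurons": n,
    }
    return ArchitectureComparison(
        scores=scores, ranking=ranking, diagnostics=diagnostics, components=components
    )
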
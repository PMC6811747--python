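"""Drug wash-in dose-response analysis.

Normalized per-electrode rate series (10 s bins, first-100-s mean = 1)
are aligned to the perfusion timeline — 2 min baseline at dose 0, a
2 min linear ramp to the final dose, then 4 min steady state — and the
wash-in bins are fit to the linear mixed-effects model

    dose_ie = beta0 + beta1 * rate_ie + u_e + eps_ie,
    u_e ~ N(0, sigma_u^2),  eps_ie ~ N(0, sigma_eps^2),

with a random intercept per electrode, by maximum likelihood.  Dose
(uM) as the response and normalized rate as the predictor —
``dose ~ 1 + normalized rate + (1|electrode)`` — is the canonical
orientation here; the conventional rate-on-dose regression is
available as a clearly-labeled secondary output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .containers import RateSeries
from .synthdata import DrugProtocol

__all__ = [
    "PerfusionExperiment",
    "build_experiment",
    "DoseResponseLME",
    "DoseResponseResults",
    "fit_dose_lme",
    "SuppressionSummary",
    "suppression_summary",
]

_NORM_TOL = 1e-6


@dataclass
class PerfusionExperiment:
    """Normalized per-electrode rates aligned to a dose timeline.

    ``data`` is tidy: one row per (electrode, bin) with columns
    trial, electrode, t_mid_s, dose_uM, norm_rate.
    """

    data: pd.DataFrame
    protocol: DrugProtocol
    trial_id: str = "trial0"

    def washin_data(self, window: tuple[float, float] | None = None) -> pd.DataFrame:
        """Rows whose bin midpoints fall in the wash-in window.

        Defaults to [baseline, baseline + ramp), i.e. 2-4 min into the
        recording under the default timeline.
        """
        if window is None:
            window = (self.protocol.baseline_s, self.protocol.baseline_s + self.protocol.ramp_s)
        lo, hi = window
        m = (self.data["t_mid_s"] >= lo) & (self.data["t_mid_s"] < hi)
        return self.data.loc[m]


def build_experiment(
    series: dict[str, RateSeries] | list[RateSeries],
    protocol: DrugProtocol,
    trial_id: str = "trial0",
) -> PerfusionExperiment:
    """Pair each electrode's normalized 10 s bins with dose(bin midpoint).

    Series must already be normalized (first ten 10 s bins averaging
    1); unnormalized input is rejected.
    """
    protocol.validate()
    if isinstance(series, list):
        series = {s.channel_id: s for s in series}
    rows = []
    for elec, s in series.items():
        if not s.normalized or abs(s.values[:10].mean() - 1.0) > _NORM_TOL:
            raise ValueError(
                f"series {elec!r} is not normalized (first-100-s mean must be 1)"
            )
        mids = s.bin_midpoints()
        doses = protocol.dose(mids)
        for t, d, r in zip(mids, doses, s.values):
            rows.append((trial_id, elec, float(t), float(d), float(r)))
    data = pd.DataFrame(
        rows, columns=["trial", "electrode", "t_mid_s", "dose_uM", "norm_rate"]
    )
    return PerfusionExperiment(data=data, protocol=protocol, trial_id=trial_id)


@dataclass
class DoseResponseResults:
    """Estimates from the dose-on-rate mixed model.

    beta0, beta1 : fixed intercept and slope (uM, uM per unit rate).
    se_beta1 : standard error of the slope.
    p_value : Wald (normal-approximation) p-value for beta1.
    sigma_u, sigma_eps : random-intercept and residual SDs (uM).
    """

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    p_value: float
    sigma_u: float
    sigma_eps: float
    n_electrodes: int
    n_observations: int
    method: str = "MixedLM-ML"
    converged: bool = True
    secondary_rate_on_dose: dict | None = None

    def summary(self) -> str:
        lines = [
            "Dose ~ 1 + normalized rate + (1 | electrode)   [ML]",
            f"  observations: {self.n_observations}   electrodes: {self.n_electrodes}",
            f"  beta0 (intercept) : {self.beta0:10.4f}  (SE {self.se_beta0:.4f})",
            f"  beta1 (rate slope): {self.beta1:10.4f}  (SE {self.se_beta1:.4f})",
            f"  Wald p(beta1)     : {self.p_value:10.3g}",
            f"  sigma_u (electrode RE SD): {self.sigma_u:.4f}",
            f"  sigma_eps (residual SD) : {self.sigma_eps:.4f}",
        ]
        if self.secondary_rate_on_dose:
            s = self.secondary_rate_on_dose
            lines.append(
                "  [non-canonical] rate ~ dose slope: "
                f"{s['slope']:.5g} (p {s['p_value']:.3g})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "se_beta0": self.se_beta0,
            "se_beta1": self.se_beta1,
            "p_value": self.p_value,
            "sigma_u": self.sigma_u,
            "sigma_eps": self.sigma_eps,
            "n_electrodes": self.n_electrodes,
            "n_observations": self.n_observations,
            "method": self.method,
            "converged": self.converged,
        }


class DoseResponseLME:
    """Mixed-effects dose model over pooled wash-in bins.

    Parameters
    ----------
    experiments : one or more PerfusionExperiment, pooled with
        electrode labels made unique across trials.
    window : wash-in window (s); defaults to each experiment's
        baseline-to-ramp-end span.

    ``fit()`` returns :class:`DoseResponseResults`.  ``force_ols=True``
    drops the random effect (the sigma_u -> 0 limit), in which case the
    slope equals the ordinary least-squares slope of dose on rate.
    """

    def __init__(
        self,
        experiments: PerfusionExperiment | list[PerfusionExperiment],
        window: tuple[float, float] | None = None,
    ) -> None:
        if isinstance(experiments, PerfusionExperiment):
            experiments = [experiments]
        if not experiments:
            raise ValueError("need at least one experiment")
        frames = []
        for exp in experiments:
            d = exp.washin_data(window).copy()
            d["electrode"] = exp.trial_id + ":" + d["electrode"].astype(str)
            frames.append(d)
        data = pd.concat(frames, ignore_index=True)
        n_elec = data["electrode"].nunique()
        if n_elec < 2:
            raise ValueError("need at least 2 electrodes")
        if data.groupby("electrode").size().min() < 3:
            raise ValueError("need at least 3 wash-in bins per electrode")
        if float(np.var(data["norm_rate"])) == 0.0:
            raise ValueError("degenerate fit: zero variance in normalized rate")
        self.data = data

    def fit(self, force_ols: bool = False) -> DoseResponseResults:
        data = self.data
        sec = self._rate_on_dose(data)
        if force_ols:
            X = sm.add_constant(data["norm_rate"].to_numpy())
            ols = sm.OLS(data["dose_uM"].to_numpy(), X).fit()
            return DoseResponseResults(
                beta0=float(ols.params[0]),
                beta1=float(ols.params[1]),
                se_beta0=float(ols.bse[0]),
                se_beta1=float(ols.bse[1]),
                p_value=float(ols.pvalues[1]),
                sigma_u=0.0,
                sigma_eps=float(np.sqrt(ols.scale)),
                n_electrodes=data["electrode"].nunique(),
                n_observations=len(data),
                method="OLS (sigma_u=0)",
                secondary_rate_on_dose=sec,
            )
        model = smf.mixedlm("dose_uM ~ norm_rate", data, groups=data["electrode"])
        import warnings

        with warnings.catch_warnings():
            # sigma_u on the boundary (zero) is a legitimate outcome
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, method="lbfgs")
        beta0, beta1 = float(res.params["Intercept"]), float(res.params["norm_rate"])
        se0, se1 = float(res.bse["Intercept"]), float(res.bse["norm_rate"])
        z = beta1 / se1 if se1 > 0 else np.inf
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = max(p, np.finfo(float).tiny)
        return DoseResponseResults(
            beta0=beta0,
            beta1=beta1,
            se_beta0=se0,
            se_beta1=se1,
            p_value=p,
            sigma_u=float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0))),
            sigma_eps=float(np.sqrt(res.scale)),
            n_electrodes=data["electrode"].nunique(),
            n_observations=len(data),
            converged=bool(res.converged),
            secondary_rate_on_dose=sec,
        )

    @staticmethod
    def _rate_on_dose(data: pd.DataFrame) -> dict:
        """Non-canonical conventional orientation, for reference only."""
        X = sm.add_constant(data["dose_uM"].to_numpy())
        ols = sm.OLS(data["norm_rate"].to_numpy(), X).fit()
        return {
            "slope": float(ols.params[1]),
            "intercept": float(ols.params[0]),
            "p_value": float(ols.pvalues[1]),
        }


def fit_dose_lme(
    experiments: PerfusionExperiment | list[PerfusionExperiment],
    window: tuple[float, float] | None = None,
    force_ols: bool = False,
) -> DoseResponseResults:
    """Convenience wrapper: build the model over pooled wash-in bins and fit."""
    return DoseResponseLME(experiments, window=window).fit(force_ols=force_ols)


@dataclass
class SuppressionSummary:
    """Steady-state activity relative to the (unit) baseline.

    Since baseline activity is normalized to 1, the mean normalized
    rate over the steady window is itself the suppression ratio.
    """

    ratio: float
    per_electrode: dict[str, float]

    @property
    def spread(self) -> float:
        vals = np.array(list(self.per_electrode.values()))
        return float(vals.std()) if vals.size else float("nan")


def suppression_summary(
    experiment: PerfusionExperiment,
    steady_window: tuple[float, float] | None = None,
) -> SuppressionSummary:
    """Mean normalized rate over the steady-state window.

    Defaults to the protocol's steady-state span (4-8 min under the
    default timeline).  Rejects an empty window.
    """
    p = experiment.protocol
    if steady_window is None:
        s0 = p.baseline_s + p.ramp_s
        steady_window = (s0, s0 + p.steady_s)
    lo, hi = steady_window
    d = experiment.data
    m = (d["t_mid_s"] >= lo) & (d["t_mid_s"] < hi)
    if not m.any():
        raise ValueError("steady window contains no bins")
    sub = d.loc[m]
    per = sub.groupby("electrode")["norm_rate"].mean().to_dict()
    return SuppressionSummary(ratio=float(sub["norm_rate"].mean()), per_electrode=per)
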
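"""Maximum-likelihood logit psychometric fitting of pooled keyword data.

Keyword outcomes from both adaptive tracks of a condition block are pooled
and fitted with a two-parameter logistic with asymptotes at 0 and 100%:

    p(snr) = 1 / (1 + exp(-(snr - alpha) / beta))

where ``alpha`` (dB) is the midpoint and ``beta > 0`` (dB) the scale.  Each
keyword contributes one Bernoulli observation at its sentence's SNR; the fit
maximises the Bernoulli likelihood by bounded quasi-Newton on
``(alpha, log beta)`` with multiple restarts.  Because the asymptotes are
fixed at 0 and 1, the speech reception threshold (SNR at 50% correct) equals
the fitted midpoint exactly.

Fit quality is summarised by r-squared between observed per-SNR proportions
and fitted values, keyword-weighted across unique SNRs (an unweighted
variant is also reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .staircase import TrialRecord

_LOG_BETA_BOUNDS = (np.log(1e-3), np.log(1e3))


class PsychometricModel:
    """Bernoulli logit model of keyword correctness vs SNR.

    Parameters
    ----------
    snr_db : array-like
        SNR (dB) of each keyword observation.
    outcomes : array-like of {0, 1}
        Whether the keyword was reported correctly.
    """

    def __init__(self, snr_db, outcomes):
        self.snr_db = np.asarray(snr_db, dtype=float)
        self.outcomes = np.asarray(outcomes, dtype=float)
        if self.snr_db.shape != self.outcomes.shape or self.snr_db.ndim != 1:
            raise ValueError("snr_db and outcomes must be 1-d arrays of equal length")
        if not np.isin(self.outcomes, (0.0, 1.0)).all():
            raise ValueError("outcomes must be binary")

    @classmethod
    def from_records(cls, records: Sequence[TrialRecord]) -> "PsychometricModel":
        """Expand trial records so every keyword is one observation at its trial SNR."""
        snrs, outs = [], []
        for r in records:
            for o in r.keyword_outcomes:
                snrs.append(r.snr_db)
                outs.append(1.0 if o else 0.0)
        return cls(snrs, outs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, snr_col: str = "snr_db",
        n_correct_col: str = "n_correct", n_keywords_col: str = "n_keywords",
    ) -> "PsychometricModel":
        """Build from a per-sentence table with keyword counts."""
        snrs, outs = [], []
        for row in df.itertuples(index=False):
            snr = getattr(row, snr_col)
            k = int(getattr(row, n_keywords_col))
            c = int(getattr(row, n_correct_col))
            snrs.extend([snr] * k)
            outs.extend([1.0] * c + [0.0] * (k - c))
        return cls(snrs, outs)

    # -- likelihood ---------------------------------------------------------

    def loglike(self, params) -> float:
        alpha, log_beta = params
        return -self._nll_grad(np.array([alpha, log_beta]))[0]

    def _nll_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        alpha, log_beta = params
        beta = np.exp(log_beta)
        z = (self.snr_db - alpha) / beta
        # log-likelihood of Bernoulli(expit(z)); stable via logaddexp
        ll = np.where(self.outcomes == 1.0, -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))
        p = expit(z)
        resid = self.outcomes - p  # d ll / d z
        d_alpha = float(np.sum(resid * (-1.0 / beta)))
        d_logbeta = float(np.sum(resid * (-z)))
        return -float(ll.sum()), -np.array([d_alpha, d_logbeta])

    def _separated(self) -> bool:
        """Complete separation: every correct keyword sits at or above every incorrect one."""
        corr = self.snr_db[self.outcomes == 1.0]
        inc = self.snr_db[self.outcomes == 0.0]
        if corr.size == 0 or inc.size == 0:
            return True
        return float(corr.min()) >= float(inc.max())

    def fit(
        self,
        start_params: tuple[float, float] | None = None,
        n_restarts: int = 3,
        tol: float = 1e-8,
    ) -> "PsychometricResults":
        """Fit by L-BFGS-B on (alpha, log beta) with restarts; honest convergence flag."""
        starts = []
        if start_params is not None:
            a0, b0 = start_params
            starts.append((a0, np.log(max(b0, 1e-3))))
        med = float(np.median(self.snr_db))
        spread = float(np.std(self.snr_db)) or 1.0
        starts += [(med, np.log(2.0)), (med - spread, np.log(4.0)), (med + spread, np.log(1.0))]

        best = None
        for s in starts[: max(n_restarts, 1) + (start_params is not None)]:
            res = minimize(
                self._nll_grad,
                np.asarray(s, dtype=float),
                jac=True,
                method="L-BFGS-B",
                bounds=[(None, None), _LOG_BETA_BOUNDS],
                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        assert best is not None
        alpha, log_beta = best.x
        beta = float(np.exp(log_beta))
        at_bound = (
            log_beta <= _LOG_BETA_BOUNDS[0] + 1e-6 or log_beta >= _LOG_BETA_BOUNDS[1] - 1e-6
        )
        converged = bool(best.success) and not at_bound and not self._separated()
        return PsychometricResults(self, float(alpha), beta, converged, -float(best.fun))


class PsychometricResults:
    """Fitted logit psychometric function.

    Attributes
    ----------
    midpoint_db, slope_db : float
        Fitted midpoint alpha and logistic scale beta (dB).
    srt_db : float
        The speech reception threshold, the SNR at 50% correct; equals the
        midpoint under the 0/100% asymptote parameterisation.  ``nan`` when
        the fit did not converge (e.g. complete separation).
    r_squared : float
        Keyword-weighted squared correlation between observed per-SNR
        proportions and fitted values.
    """

    def __init__(
        self,
        model: PsychometricModel,
        midpoint_db: float,
        slope_db: float,
        converged: bool,
        llf: float,
    ):
        self.model = model
        self.midpoint_db = midpoint_db
        self.slope_db = slope_db
        self.converged = converged
        self.llf = llf
        self.n_keywords_total = int(model.outcomes.size)

    @property
    def srt_db(self) -> float:
        return self.midpoint_db if self.converged else float("nan")

    def predict(self, snr_db) -> np.ndarray:
        """Fitted P(keyword correct) at the given SNR(s)."""
        z = (np.asarray(snr_db, dtype=float) - self.midpoint_db) / self.slope_db
        return expit(z)

    # -- uncertainty --------------------------------------------------------

    def cov_params(self) -> np.ndarray:
        """Asymptotic covariance of (alpha, beta) from the observed information."""
        a, b = self.midpoint_db, self.slope_db
        z = (self.model.snr_db - a) / b
        w = expit(z) * (1.0 - expit(z))
        # Fisher information in (alpha, beta) for the Bernoulli logit
        i_aa = np.sum(w) / b**2
        i_ab = np.sum(w * z) / b**2
        i_bb = np.sum(w * z**2) / b**2
        info = np.array([[i_aa, i_ab], [i_ab, i_bb]])
        try:
            return np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)

    @property
    def bse(self) -> np.ndarray:
        cov = self.cov_params()
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(cov))

    # -- fit quality --------------------------------------------------------

    def _binned(self) -> pd.DataFrame:
        df = pd.DataFrame({"snr": self.model.snr_db, "y": self.model.outcomes})
        g = df.groupby("snr", sort=True)["y"].agg(["mean", "count"]).reset_index()
        g["fitted"] = self.predict(g["snr"].to_numpy())
        return g

    def _r2(self, weighted: bool) -> float:
        g = self._binned()
        if len(g) < 3:
            return float("nan")
        x = g["mean"].to_numpy()
        y = g["fitted"].to_numpy()
        w = g["count"].to_numpy(dtype=float) if weighted else np.ones(len(g))
        w = w / w.sum()
        mx, my = np.sum(w * x), np.sum(w * y)
        cov = np.sum(w * (x - mx) * (y - my))
        vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
        if vx <= 0 or vy <= 0:
            return 0.0
        return float(cov**2 / (vx * vy))

    @property
    def r_squared(self) -> float:
        return self._r2(weighted=True)

    @property
    def r_squared_unweighted(self) -> float:
        return self._r2(weighted=False)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Psychometric fit (logit, asymptotes 0/100%)",
            f"  n keywords        {self.n_keywords_total}",
            f"  midpoint (dB)     {self.midpoint_db: .3f}  (SE {se[0]:.3f})",
            f"  slope (dB)        {self.slope_db: .3f}  (SE {se[1]:.3f})",
            f"  SRT (dB SNR)      {self.srt_db: .3f}",
            f"  r-squared         {self.r_squared: .4f}",
            f"  converged         {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed per-SNR proportions (sized by keyword count) with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self._binned()
        ax.scatter(g["snr"], g["mean"], s=10 * g["count"], alpha=0.6, label="observed")
        xs = np.linspace(g["snr"].min() - 2, g["snr"].max() + 2, 200)
        ax.plot(xs, self.predict(xs), label="fitted logit")
        if self.converged:
            ax.axvline(self.srt_db, ls="--", c="grey", lw=1)
            ax.axhline(0.5, ls="--", c="grey", lw=1)
        ax.set_xlabel("SNR (dB)")
        ax.set_ylabel("P(keyword correct)")
        ax.legend()
        return ax


def fit_logit(records: Sequence[TrialRecord], **fit_kwargs) -> PsychometricResults:
    """Pool keyword data from the given trial records and fit the logit."""
    return PsychometricModel.from_records(records).fit(**fit_kwargs)
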
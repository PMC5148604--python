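"""Probit dose-response analysis: LD50 / ED50 estimation.

Survival counts at each dose are modeled by binomial maximum likelihood with
a probit link, ``P(survive) = Phi(a + b * dose)`` (optionally log10 dose for
metabolic titrations such as glucose withdrawal).  The median lethal dose is
the dose at which fitted survival is 50%, ``LD50 = -a / b``, with a
delta-method standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


class NonIdentifiableError(ValueError):
    """The probit line is not identifiable (separation or constant outcome)."""


@dataclass
class DoseResponseFit:
    intercept: float
    slope: float
    ld50: float
    ld50_se: float
    log10_dose: bool
    n_doses: int

    def predict(self, dose):
        from scipy.stats import norm
        d = np.log10(np.asarray(dose, dtype=float)) if self.log10_dose \
            else np.asarray(dose, dtype=float)
        return norm.cdf(self.intercept + self.slope * d)


def probit_ld50(doses, survived, total, log10_dose: bool = False
                ) -> DoseResponseFit:
    """Fit the probit survival line and back out the LD50 (or ED50).

    ``doses`` must contain at least 3 distinct values; survival counts must
    satisfy ``0 <= survived <= total``.  Raises
    :class:`NonIdentifiableError` when all outcomes are identical or the fit
    separates completely.
    """
    doses = np.asarray(doses, dtype=float)
    survived = np.asarray(survived, dtype=float)
    total = np.asarray(total, dtype=float)
    if doses.size != survived.size or doses.size != total.size:
        raise ValueError("doses, survived and total must have equal length")
    if np.unique(doses).size < 3:
        raise ValueError("need at least 3 distinct doses")
    if (doses <= 0).any() and log10_dose:
        raise ValueError("log10 dose scale requires positive doses")
    if (survived < 0).any() or (survived > total).any() or (total <= 0).any():
        raise ValueError("need 0 <= survived <= total with positive totals")
    frac = survived / total
    if np.all(frac == frac[0]):
        raise NonIdentifiableError("all doses gave the same outcome")
    x = np.log10(doses) if log10_dose else doses
    exog = sm.add_constant(x)
    endog = np.column_stack([survived, total - survived])
    model = sm.GLM(endog, exog,
                   family=sm.families.Binomial(sm.families.links.Probit()))
    try:
        res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:
        raise NonIdentifiableError(f"probit fit failed: {exc}") from exc
    a, b = res.params
    if not np.isfinite([a, b]).all() or abs(b) < 1e-12:
        raise NonIdentifiableError("slope not identifiable (flat response)")
    ld50_lin = -a / b
    cov = res.cov_params()
    grad = np.array([-1.0 / b, a / b ** 2])
    var = float(grad @ cov @ grad)
    se_lin = np.sqrt(max(var, 0.0))
    if log10_dose:
        ld50 = 10.0 ** ld50_lin
        ld50_se = ld50 * np.log(10.0) * se_lin  # delta method through 10**x
    else:
        ld50, ld50_se = ld50_lin, se_lin
    return DoseResponseFit(intercept=float(a), slope=float(b),
                           ld50=float(ld50), ld50_se=float(ld50_se),
                           log10_dose=log10_dose,
                           n_doses=int(np.unique(doses).size))


def read_dose_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"dose", "n_survived", "n_total"}
    if not need <= set(df.columns):
        raise ValueError(f"dose table needs columns {sorted(need)}")
    return df
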
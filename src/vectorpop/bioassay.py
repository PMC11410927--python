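"""WHO tube-bioassay statistics and field-collection proportion summaries.

Mortality follows the WHO tube-test rules: Abbott correction when control
mortality falls in [5%, 20%], test invalid above 20% control mortality;
classification thresholds are >= 98% susceptible, 90-98% suspected
resistance, < 90% resistant. Confidence intervals use the Newcombe-recommended
Wilson score interval. Site/insecticide comparisons use a binomial GLM with a
logit link (tubes pooled per site x insecticide cell), with per-term Wald
chi-square tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Z95 = 1.959964

#: Abbott-correction band and validity cutoff on control mortality (%), from
#: the WHO tube-test protocol; exposed in config rather than buried in logic
ABBOTT_BAND = (5.0, 20.0)
CONTROL_INVALID_ABOVE = 20.0

#: WHO classification thresholds (% mortality)
SUSCEPTIBLE_MIN = 98.0
RESISTANT_BELOW = 90.0


@dataclass
class BioassayRecord:
    site: str
    subsite: str
    insecticide: str
    n_exposed: int
    n_dead: int
    control_n: int = 0
    control_dead: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValueError("need 0 <= n_dead <= n_exposed")
        if not 0 <= self.control_dead <= max(self.control_n, 0):
            raise ValueError("need 0 <= control_dead <= control_n")


@dataclass
class MortalitySummary:
    site: str
    subsite: str
    insecticide: str
    percent_mortality: float
    corrected: bool
    ci_low: float = math.nan  # percent scale
    ci_high: float = math.nan
    status: str | None = None


@dataclass
class GlmFit:
    coefficients: "pd.Series"
    standard_errors: "pd.Series"
    wald_chi2: dict[str, float]  # per design term
    df: dict[str, int]
    p_values: dict[str, float]
    deviance: float
    converged: bool
    warnings: list[str] = field(default_factory=list)


def mortality(
    rec: BioassayRecord,
    abbott_band: tuple[float, float] = ABBOTT_BAND,
    invalid_above: float = CONTROL_INVALID_ABOVE,
) -> MortalitySummary:
    """Percent mortality with Abbott control correction where the WHO rules apply.

    Control mortality below the Abbott band leaves the raw value; inside
    [5%, 20%] the corrected value is (raw - c) / (100 - c) * 100; above 20%
    the test is invalid.
    """
    if rec.n_exposed == 0:
        raise ValueError("n_exposed must be > 0")
    raw = 100.0 * rec.n_dead / rec.n_exposed
    control_pct = 100.0 * rec.control_dead / rec.control_n if rec.control_n else 0.0
    if control_pct > invalid_above:
        return MortalitySummary(
            rec.site, rec.subsite, rec.insecticide, raw, False, status="invalid"
        )
    if abbott_band[0] <= control_pct <= abbott_band[1]:
        corrected = (raw - control_pct) / (100.0 - control_pct) * 100.0
        return MortalitySummary(
            rec.site, rec.subsite, rec.insecticide, corrected, True
        )
    return MortalitySummary(rec.site, rec.subsite, rec.insecticide, raw, False)


def newcombe_ci(
    k: int, n: int, level: float = 0.95, continuity: bool = False
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (Newcombe's single-proportion method).

    The continuity-corrected variant is available behind ``continuity``; the
    default matches the plain score interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    from scipy.stats import norm

    z = float(norm.ppf(1 - (1 - level) / 2))
    phat = k / n
    if continuity:
        # Newcombe (1998) method 4
        denom = 2 * (n + z**2)
        low_num = 2 * k + z**2 - 1 - z * math.sqrt(z**2 - 2 - 1 / n + 4 * phat * (n * (1 - phat) + 1))
        high_num = 2 * k + z**2 + 1 + z * math.sqrt(z**2 + 2 - 1 / n + 4 * phat * (n * (1 - phat) - 1))
        low = 0.0 if k == 0 else max(0.0, low_num / denom)
        high = 1.0 if k == n else min(1.0, high_num / denom)
        return low, high
    centre = (phat + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
    low = 0.0 if k == 0 else max(0.0, centre - half)  # boundary cases are exact
    high = 1.0 if k == n else min(1.0, centre + half)
    return low, high


def classify_resistance(percent_mortality: float) -> str:
    """WHO classification: < 90 resistant, 90-98 suspected, >= 98 susceptible."""
    if not 0.0 <= percent_mortality <= 100.0:
        raise ValueError(f"mortality must be in [0, 100], got {percent_mortality}")
    if percent_mortality < RESISTANT_BELOW:
        return "resistant"
    if percent_mortality < SUSCEPTIBLE_MIN:
        return "suspected_resistance"
    return "susceptible"


def summarize_bioassay(records: list[BioassayRecord]) -> list[MortalitySummary]:
    """Full per-record summary: corrected mortality, Wilson 95% CI (%), WHO status."""
    out = []
    for rec in records:
        summ = mortality(rec)
        lo, hi = newcombe_ci(rec.n_dead, rec.n_exposed)
        summ.ci_low, summ.ci_high = 100 * lo, 100 * hi
        if summ.status != "invalid":
            summ.status = classify_resistance(min(max(summ.percent_mortality, 0.0), 100.0))
        out.append(summ)
    return out


def fit_binomial_glm(
    records: list[BioassayRecord],
    design: str = "site + insecticide",
) -> GlmFit:
    """Binomial (logit) GLM of dead/exposed counts on design factors.

    ``design`` is a formula right-hand side over the record fields (site,
    subsite, insecticide). Cells are the site x insecticide aggregates with
    tubes pooled. Per-term Wald chi-square statistics and p-values come from
    joint tests of each term's coefficients; single-df terms satisfy
    chi2 = (coef/SE)^2. Complete separation is flagged as non-converged and
    the fit still returned with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(records) < 2:
        raise ValueError("need at least 2 design cells")
    df = pd.DataFrame(
        {
            "site": [r.site for r in records],
            "subsite": [r.subsite for r in records],
            "insecticide": [r.insecticide for r in records],
            "dead": [r.n_dead for r in records],
            "alive": [r.n_exposed - r.n_dead for r in records],
        }
    )
    model = smf.glm(f"dead + alive ~ {design}", data=df, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-12)
    warnings_list: list[str] = []
    fitted = np.asarray(res.mu)
    converged = bool(res.converged)
    if np.any(fitted < 1e-8) or np.any(fitted > 1 - 1e-8):
        converged = False
        warnings_list.append(
            "fitted probabilities at the 0/1 boundary: possible complete separation;"
            " coefficients unreliable"
        )
    wt = res.wald_test_terms(scalar=True)
    table = wt.table
    return GlmFit(
        coefficients=res.params,
        standard_errors=res.bse,
        wald_chi2={term: float(row["statistic"]) for term, row in table.iterrows()},
        df={term: int(row["df_constraint"]) for term, row in table.iterrows()},
        p_values={term: float(row["pvalue"]) for term, row in table.iterrows()},
        deviance=float(res.deviance),
        converged=converged,
        warnings=warnings_list,
    )


def proportion_summary(k: int, n: int) -> tuple[float, tuple[float, float]]:
    """Percent (1 decimal) with Wilson 95% CI, for field-collection proportions.

    Example: 730 of 866 blood-fed gives (84.3, (81.7, 86.6)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pct = round(100.0 * k / n, 1)
    lo, hi = newcombe_ci(k, n)
    return pct, (round(100 * lo, 1), round(100 * hi, 1))


def read_bioassay_tsv(path) -> list[BioassayRecord]:
    """Read bioassay TSV: site, subsite, insecticide, n_exposed, n_dead, control_n, control_dead."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        BioassayRecord(
            site=row.site,
            subsite=row.subsite,
            insecticide=row.insecticide,
            n_exposed=int(row.n_exposed),
            n_dead=int(row.n_dead),
            control_n=int(getattr(row, "control_n", 0)),
            control_dead=int(getattr(row, "control_dead", 0)),
        )
        for row in df.itertuples()
    ]
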
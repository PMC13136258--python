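"""Per-trait phenotypic diversity statistics.

Quantitative traits are summarised by mean, sample SD (n-1 denominator),
range and the coefficient of variation CV = sigma/mu x 100 (%).  Trait
diversity uses the seven-level sigma-interval classification: each value
is binned by its distance from the trait mean in units of SD
(cut points mu +/- 0.5 sigma, mu +/- 1.5 sigma, mu +/- 2.5 sigma, intervals
half-open and lower-closed; the bottom class absorbs everything below
mu - 2.5 sigma and the top class everything at or above mu + 2.5 sigma),
and the Shannon-Wiener index H' = -sum Pi ln Pi is taken over the level
frequencies.  Qualitative traits use their code frequencies directly.
A fixed-effects two-way Year x Variety ANOVA with interaction serves the
multi-year design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TraitStats:
    trait: str
    mean: float
    sd: float
    max: float
    min: float
    cv: float  # percent; NaN when mean == 0
    h_prime: float | None = None  # filled by quantitative_diversity
    n_used: int = 0


@dataclass
class LevelAssignment:
    """Seven-level classification of a quantitative trait.

    ``levels`` holds each non-missing value's level in 1..7; ``cuts`` the
    six cut points (mu-2.5s, mu-1.5s, mu-0.5s, mu+0.5s, mu+1.5s, mu+2.5s);
    ``frequencies`` the relative frequencies P1..P7 over non-missing values.
    """

    levels: np.ndarray
    cuts: np.ndarray
    frequencies: np.ndarray


@dataclass
class CorrelationMatrix:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """Three-level significance stars: * <0.05, ** <0.01, *** <0.001."""
        def star(p: float) -> str:
            if np.isnan(p):
                return ""
            if p < 0.001:
                return "***"
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return "ns"

        return self.p.map(star)

    def to_long(self) -> pd.DataFrame:
        """Long-format (trait_a, trait_b, r, p, stars) for heat-map export."""
        rows = []
        stars = self.stars()
        for i, a in enumerate(self.traits):
            for b in self.traits[i + 1:]:
                rows.append(
                    {"trait_a": a, "trait_b": b, "r": self.r.loc[a, b],
                     "p": self.p.loc[a, b], "n": self.n.loc[a, b],
                     "stars": stars.loc[a, b]}
                )
        return pd.DataFrame(rows)


def trait_stats(values, *, trait: str = "") -> TraitStats:
    """Descriptive statistics with the sample (n-1) standard deviation.

    CV is reported as a percentage of the mean; a zero mean makes CV
    undefined and it is returned as NaN with a warning.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size == 0:
        raise ValueError(f"trait {trait!r}: all values missing")
    if v.size < 2:
        raise ValueError(f"trait {trait!r}: need >= 2 non-missing values")
    mu = float(np.mean(v))
    sigma = float(np.std(v, ddof=1))
    if mu == 0.0:
        warnings.warn(f"trait {trait!r}: mean is 0, CV undefined")
        cv = float("nan")
    else:
        cv = sigma / mu * 100.0
    return TraitStats(
        trait=trait, mean=mu, sd=sigma, max=float(np.max(v)), min=float(np.min(v)),
        cv=cv, n_used=int(v.size),
    )


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV (%) = sd / mean x 100, the identity used throughout Table-style
    summaries.  Undefined (NaN) at mean zero."""
    if mean == 0:
        return float("nan")
    return sd / mean * 100.0


def assign_levels(values, mu: float, sigma: float) -> LevelAssignment:
    """Classify values into the seven half-open sigma intervals.

    Level 1 is x < mu - 2.5 sigma; level k (2..6) is
    mu + (k - 4.5) sigma <= x < mu + (k - 3.5) sigma; level 7 is
    x >= mu + 2.5 sigma.  A degenerate trait (sigma = 0) puts everything
    in the central level 4 with a warning.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size == 0:
        raise ValueError("no non-missing values to classify")
    cuts = mu + sigma * np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
    if sigma == 0:
        warnings.warn("sigma is 0: degenerate trait, all values assigned level 4")
        levels = np.full(v.size, 4, dtype=int)
    elif sigma < 0:
        raise ValueError("sigma must be non-negative")
    else:
        levels = np.digitize(v, cuts, right=False) + 1  # lower-closed intervals
    freqs = np.bincount(levels, minlength=8)[1:8] / v.size
    return LevelAssignment(levels=levels, cuts=cuts, frequencies=freqs)


def shannon_index(frequencies) -> float:
    """Shannon-Wiener H' = -sum Pi ln Pi in nats (0 ln 0 := 0)."""
    p = np.asarray(frequencies, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum():.12g}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def quantitative_diversity(values) -> float:
    """H' of a quantitative trait: seven-level binning then Shannon index."""
    s = trait_stats(values)
    assignment = assign_levels(values, s.mean, s.sd)
    return shannon_index(assignment.frequencies)


@dataclass
class QualitativeDistribution:
    trait: str
    codes: list[int]
    percent: np.ndarray  # distribution frequency (%) per code, over non-missing
    cv: float  # percent, computed on the numeric codes (scale-dependent)
    h_prime: float
    n_used: int


def qualitative_distribution(codes, *, trait: str = "",
                             declared_codes=None) -> QualitativeDistribution:
    """Frequency distribution, CV and H' for a coded qualitative trait.

    H' is taken over the observed code frequencies.  CV is sigma/mu on the
    integer codes themselves, which depends on the (arbitrary) coding
    scale; it is reported because descriptor-standard summaries
    conventionally print it, not because it is scale-free.
    """
    v = pd.Series(codes).dropna().astype(int)
    if v.empty:
        raise ValueError(f"trait {trait!r}: no non-missing codes")
    if declared_codes is not None:
        bad = sorted(set(v) - set(declared_codes))
        if bad:
            raise ValueError(f"trait {trait!r}: codes {bad} outside declared set")
    counts = v.value_counts().sort_index()
    freqs = counts / counts.sum()
    s = trait_stats(v, trait=trait)
    return QualitativeDistribution(
        trait=trait,
        codes=[int(c) for c in counts.index],
        percent=freqs.to_numpy() * 100.0,
        cv=s.cv,
        h_prime=shannon_index(freqs.to_numpy()),
        n_used=int(v.size),
    )


def correlation_matrix(table, traits: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided t-test p-values.

    ``table`` is a TraitTable or a DataFrame of numeric columns.  A pair
    needs at least 3 complete observations; zero-variance traits yield
    NaN for their pairs.
    """
    df = table.values if hasattr(table, "values") and hasattr(table, "trait_names") else table
    if traits is None:
        traits = list(df.columns)
    df = df[traits].astype(float)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        n[i, i] = int(df[traits[i]].notna().sum())
        for j in range(i + 1, k):
            pair = df[[traits[i], traits[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(traits)
    return CorrelationMatrix(
        traits=traits,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


@dataclass
class AnovaTable:
    """Two-way fixed-effects ANOVA decomposition for one trait.

    ``table`` rows are the sources Year, Variety, Year x Variety, Error
    with columns df, ss, ms, F, p, stars (stars: * at 0.05, ** at 0.01).
    """

    trait: str
    table: pd.DataFrame

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]


def _anova_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def two_way_anova(values, year, variety, *, trait: str = "") -> AnovaTable:
    """Fixed-effects two-way ANOVA with interaction (Year, Variety,
    Year x Variety, Error), F = MS_source / MS_error.

    On balanced data the sums of squares come from the exact cell-mean
    decomposition (so SS_total = sum of the parts).  Unbalanced input
    triggers a warning and sequential (type-I) SS in Year, Variety,
    interaction order via an OLS fit.  A design without replication
    within cells cannot estimate the interaction and raises.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "year": np.asarray(year),
                       "variety": np.asarray(variety)}).dropna()
    years = df["year"].unique()
    varieties = df["variety"].unique()
    a, b = len(years), len(varieties)
    if a < 2 or b < 2:
        raise ValueError("need >= 2 years and >= 2 varieties")
    cell_sizes = df.groupby(["year", "variety"], observed=True)["y"].size()
    if len(cell_sizes) < a * b:
        raise ValueError("empty year x variety cells: design not crossed")
    if (cell_sizes < 2).all():
        raise ValueError(
            "single replicate per cell: interaction inestimable; pool replicates "
            "or drop the interaction term"
        )
    balanced = cell_sizes.nunique() == 1

    if balanced:
        n = int(cell_sizes.iloc[0])
        grand = df["y"].mean()
        ym = df.groupby("year", observed=True)["y"].mean()
        vm = df.groupby("variety", observed=True)["y"].mean()
        cm = df.groupby(["year", "variety"], observed=True)["y"].mean()
        ss_year = b * n * float(((ym - grand) ** 2).sum())
        ss_var = a * n * float(((vm - grand) ** 2).sum())
        ss_cells = n * float(((cm - grand) ** 2).sum())
        ss_int = ss_cells - ss_year - ss_var
        ss_tot = float(((df["y"] - grand) ** 2).sum())
        ss_err = ss_tot - ss_cells
        df_year, df_var = a - 1, b - 1
        df_int = (a - 1) * (b - 1)
        df_err = len(df) - a * b
        ss = np.array([ss_year, ss_var, ss_int, ss_err])
        dof = np.array([df_year, df_var, df_int, df_err])
    else:
        warnings.warn(
            f"trait {trait!r}: unbalanced design, using sequential (type-I) SS "
            "in Year, Variety, interaction order"
        )
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        fit = smf.ols("y ~ C(year) * C(variety)", data=df).fit()
        aov = sm.stats.anova_lm(fit, typ=1)
        ss = aov["sum_sq"].to_numpy()
        dof = aov["df"].to_numpy().astype(int)

    ms = ss / dof
    ms_err = ms[3]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.arange(4) < 3, ms / ms_err if ms_err > 0 else np.nan, np.nan)
    pvals = np.full(4, np.nan)
    for i in range(3):
        if np.isfinite(f[i]):
            pvals[i] = stats.f.sf(f[i], dof[i], dof[3])
    out = pd.DataFrame(
        {
            "df": dof,
            "ss": ss,
            "ms": ms,
            "F": f,
            "p": pvals,
            "stars": [_anova_stars(p) for p in pvals],
        },
        index=pd.Index(["Year", "Variety", "Year x Variety", "Error"], name="source"),
    )
    return AnovaTable(trait=trait, table=out)


def trait_summary_table(table) -> pd.DataFrame:
    """Per-trait descriptive summary: quantitative traits get mean, SD,
    max, min, CV(%) and the seven-level H'; qualitative traits get CV and
    H' from their code frequencies."""
    rows = []
    for t in table.trait_names:
        col = table.trait(t)
        if table.schema.is_qualitative(t):
            q = qualitative_distribution(col, trait=t,
                                         declared_codes=table.schema.codes[t])
            rows.append({"trait": t, "kind": "qualitative", "mean": np.nan,
                         "sd": np.nan, "max": np.nan, "min": np.nan,
                         "cv": q.cv, "h_prime": q.h_prime, "n": q.n_used})
        else:
            s = trait_stats(col, trait=t)
            h = quantitative_diversity(col)
            rows.append({"trait": t, "kind": "quantitative", "mean": s.mean,
                         "sd": s.sd, "max": s.max, "min": s.min,
                         "cv": s.cv, "h_prime": h, "n": s.n_used})
    return pd.DataFrame(rows).set_index("trait")
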
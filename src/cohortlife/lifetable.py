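"""Abridged (Chiang) life table and the sampling variance of life expectancy.

Given deaths ``D_j`` and person-years ``PY_j`` per age band, the abridged
life table converts the age-specific death rate ``m_j = D_j / PY_j`` into
the conditional probability of dying in the band,

    q_j = n_j m_j / (1 + n_j (1 - a_j) m_j),        clamped at 1,

propagates a synthetic cohort of ``radix`` people through the bands
(``l``, ``d``, ``L``, ``T``) and reports remaining life expectancy
``e_j = T_j / l_j`` at the start of each band.  The terminal open band is
treated as exponential: ``q_w = 1``, ``L_w = l_w / m_w`` and
``e_w = 1 / m_w`` (a fixed terminal expectancy can be supplied instead).

The sampling variance of ``e_i`` treats the band survival probabilities as
independent binomial-type estimates with

    S²(p_j) = q_j² p_j / D_j            (0 when D_j = 0, since then q_j = 0)

and accumulates

    Var(e_i) = (1/l_i²) · Σ_{j=i}^{w-1} l_j² [(1-a_j) n_j + e_{j+1}]² S²(p_j)
               + (l_w/l_i)² · Var(e_w),

where ``Var(e_w) = 1 / (m_w² D_w)`` is the delta-method variance of the
terminal exponential expectancy under a Poisson death count (zero when the
terminal expectancy is fixed by configuration).  The 95% confidence
interval is ``e ± 1.96·SE``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .bands import AgeBandSchema
from .errors import LifeTableError
from .exposure import ExposureTable

__all__ = [
    "LifeTable",
    "rate_to_probability",
    "build_life_table",
    "variance_of_life_expectancy",
    "confidence_interval",
]


def rate_to_probability(m, n, a):
    """Convert a central death rate to a probability of dying in the interval.

    ``q = n·m / (1 + n·(1-a)·m)``, clamped to at most 1.  Accepts scalars or
    arrays.  ``m`` must be non-negative, ``n`` positive, ``a`` in [0, 1].
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(m < 0):
        raise ValueError("death rate m must be non-negative")
    if np.any(n <= 0):
        raise ValueError("interval width n must be positive")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("a must lie in [0, 1]")
    q = n * m / (1.0 + n * (1.0 - a) * m)
    q = np.minimum(q, 1.0)
    return float(q) if q.ndim == 0 else q


def confidence_interval(e, se, level: float = 0.95):
    """Symmetric normal interval ``e ± z·SE`` (z = 1.96 at the 95% level)."""
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr[np.isfinite(se_arr)] < 0):
        raise ValueError("standard error must be non-negative")
    z = 1.96 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    e_arr = np.asarray(e, dtype=float)
    lo, hi = e_arr - z * se_arr, e_arr + z * se_arr
    if e_arr.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


@dataclass
class LifeTable:
    """Per-band life-table columns; arrays are aligned with ``schema.bands``.

    Rows where the synthetic cohort is extinct (``l = 0``) carry NaN life
    expectancy; they cannot occur above the first band with survivors.
    """

    schema: AgeBandSchema
    radix: float
    m: np.ndarray
    q: np.ndarray
    p: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray
    var_p: np.ndarray
    se_e: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    deaths: np.ndarray
    person_years: np.ndarray
    group_label: Optional[str] = None

    @property
    def e0(self) -> float:
        """Life expectancy at the start of the first band."""
        return float(self.e[0])

    @property
    def se0(self) -> float:
        return float(self.se_e[0])

    def to_frame(self) -> pd.DataFrame:
        widths = self.schema.widths
        return pd.DataFrame(
            {
                "band": self.schema.labels,
                "band_start": self.schema.starts,
                "band_width": np.where(np.isinf(widths), np.nan, widths),
                "a": self.schema.a_values,
                "deaths": self.deaths,
                "person_years": self.person_years,
                "m": self.m,
                "q": self.q,
                "p": self.p,
                "l": self.l,
                "d": self.d,
                "L": self.L,
                "T": self.T,
                "e": self.e,
                "var_p": self.var_p,
                "se_e": self.se_e,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = self.to_frame().to_json(orient="records", indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_text(self, decimals: int = 1) -> str:
        df = self.to_frame()
        lines = [f"{'band':>8} {'deaths':>8} {'py':>12} {'e':>8} {'95% CI':>16}"]
        for _, r in df.iterrows():
            if np.isnan(r["e"]):
                lines.append(f"{r['band']:>8} {int(r['deaths']):>8} {r['person_years']:>12.1f} {'--':>8}")
                continue
            ci = f"({r['ci_low']:.{decimals}f}, {r['ci_high']:.{decimals}f})"
            lines.append(
                f"{r['band']:>8} {int(r['deaths']):>8} {r['person_years']:>12.1f} "
                f"{r['e']:>8.{decimals}f} {ci:>16}"
            )
        return "\n".join(lines)


def build_life_table(
    exposure: ExposureTable,
    radix: float = 100_000.0,
    level: float = 0.95,
    terminal_e_fixed: Optional[float] = None,
) -> LifeTable:
    """Build the abridged life table from per-band deaths and person-years.

    Raises :class:`LifeTableError` if a closed band still reached by the
    synthetic cohort has zero person-years (merge bands), or if the terminal
    band is reached but recorded no deaths (extend the open band), since the
    terminal expectancy ``1/m_w`` is then undefined.  Bands below an extinct
    cohort (``l = 0``, which happens when some ``q`` clamps to 1) are inert:
    they do not constrain the input and carry zero flow.
    """
    if radix <= 0:
        raise ValueError("radix must be positive")
    schema = exposure.schema
    w = len(schema)
    D = np.asarray(exposure.deaths, dtype=float)
    PY = np.asarray(exposure.person_years, dtype=float)
    n = schema.widths
    a = schema.a_values

    m = np.zeros(w)
    q = np.zeros(w)
    l = np.zeros(w)
    d = np.zeros(w)
    L = np.zeros(w)
    e_terminal_var = 0.0

    l[0] = radix
    for j in range(w - 1):
        if l[j] <= 0.0:
            continue  # cohort extinct: rows below carry no flow
        if PY[j] <= 0.0:
            raise LifeTableError(
                f"closed band {schema.bands[j].label} has zero person-years but is "
                "still reached by the cohort; merge age bands"
            )
        m[j] = D[j] / PY[j]
        q[j] = rate_to_probability(m[j], n[j], a[j])
        d[j] = l[j] * q[j]
        l[j + 1] = l[j] - d[j]
        L[j] = n[j] * (l[j + 1] + a[j] * d[j])

    # terminal open band
    q[w - 1] = 1.0
    d[w - 1] = l[w - 1]
    if l[w - 1] > 0.0:
        if terminal_e_fixed is not None:
            if terminal_e_fixed <= 0:
                raise LifeTableError("terminal_e_fixed must be positive")
            L[w - 1] = l[w - 1] * terminal_e_fixed
            m[w - 1] = 1.0 / terminal_e_fixed
        else:
            if D[w - 1] <= 0.0:
                raise LifeTableError(
                    f"terminal band {schema.bands[w - 1].label} reached by the cohort "
                    "but has no deaths; terminal life expectancy 1/m is undefined — "
                    "extend the open band"
                )
            if PY[w - 1] <= 0.0:
                raise LifeTableError(
                    f"terminal band {schema.bands[w - 1].label} has deaths but zero person-years"
                )
            m[w - 1] = D[w - 1] / PY[w - 1]
            L[w - 1] = l[w - 1] / m[w - 1]
            e_terminal_var = 1.0 / (m[w - 1] ** 2 * D[w - 1])

    p = 1.0 - q
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), np.nan)

    var_p = np.zeros(w)
    pos = D > 0
    var_p[pos] = q[pos] ** 2 * p[pos] / D[pos]

    se = variance_of_life_expectancy(
        l=l, e=e, var_p=var_p, n=n, a=a, terminal_var=e_terminal_var
    )
    ci_low, ci_high = confidence_interval(e, se, level)
    return LifeTable(
        schema=schema,
        radix=radix,
        m=m,
        q=q,
        p=p,
        l=l,
        d=d,
        L=L,
        T=T,
        e=e,
        var_p=var_p,
        se_e=se,
        ci_low=ci_low,
        ci_high=ci_high,
        deaths=D.copy(),
        person_years=PY.copy(),
        group_label=exposure.group_label,
    )


def variance_of_life_expectancy(
    l: np.ndarray,
    e: np.ndarray,
    var_p: np.ndarray,
    n: np.ndarray,
    a: np.ndarray,
    terminal_var: float = 0.0,
) -> np.ndarray:
    """Standard error of ``e_i`` for every band, by the Chiang accumulation.

    ``terminal_var`` is Var(e_w) of the open band (``1/(m_w² D_w)`` under the
    exponential-tail convention, 0 when the terminal expectancy is fixed).
    Bands with ``var_p = 0`` (no deaths, or extinct cohort) contribute
    nothing, so NaN expectancies below an extinct cohort never propagate.
    """
    w = len(l)
    # per-band contribution l_j^2 [(1-a_j) n_j + e_{j+1}]^2 S^2(p_j), j < w
    contrib = np.zeros(w)
    for j in range(w - 1):
        if var_p[j] == 0.0:
            continue
        bracket = (1.0 - a[j]) * n[j] + e[j + 1]
        contrib[j] = l[j] ** 2 * bracket**2 * var_p[j]
    contrib_terminal = l[w - 1] ** 2 * terminal_var

    se = np.full(w, np.nan)
    for i in range(w):
        if l[i] <= 0:
            continue
        acc = contrib[i : w - 1].sum() + contrib_terminal
        se[i] = np.sqrt(acc) / l[i]
    return se
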
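"""Synthetic participant cohorts with the battery's assumed causal structure.

The generator draws standardized scores from a linear latent-variable system
-- age driving pure-tone average (PTA), age and PTA driving a latent
figure-ground ability (AFG) measured by the three AFG tasks, and AFG, PTA
and age driving a latent speech-in-noise ability (SIN) measured by the word
(WiN) and sentence (SiB) tests -- then maps them onto each test's natural
scale.  Score conventions follow the battery: AFG and SiB thresholds in dB
SNR (higher = worse), WiN as proportion correct (higher = better), so the
analysis layer's sign flip of WiN is exercised.  SSQ (self-report, 0-10) is
generated independent of SIN, mirroring its observed lack of correlation
with the speech measures.

Default path coefficients are calibrated so the simulated Spearman matrix
approximates the study's published correlation table (derivation in
``docs/methods.md``); :func:`implied_spearman` returns the exact
model-implied values via the Gaussian-copula relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "CohortParams",
    "COLUMNS",
    "cohort_defaults",
    "simulate_cohort",
    "implied_correlations",
    "implied_spearman",
]

COLUMNS = ("age", "PTA", "AFG_fixed", "AFG_low", "AFG_high", "WiN", "SiB", "SSQ")

#: Natural-scale (mean, sd) of each threshold-style score (battery Table of
#: descriptive statistics); WiN is handled by the logistic squash below.
SCALE = {
    "PTA": (13.51, 10.05),
    "AFG_fixed": (-14.542, 8.200),
    "AFG_low": (8.991, 10.897),
    "AFG_high": (7.252, 10.447),
    "SiB": (-0.880, 2.114),
}

# Logistic map z -> proportion correct giving WiN mean 0.673, sd 0.107.
_WIN_ALPHA = 0.7649
_WIN_BETA = 0.5095


@dataclass(frozen=True)
class CohortParams:
    """Standardized path coefficients and score-scale settings.

    All paths are on the standardized (unit-variance) scale.  ``age_to_win``
    is the direct age effect on the word score over and above the latent SIN
    route.  ``dyn_residual_corr`` is the correlation between the low- and
    high-frequency dynamic tasks' residuals (they share method variance).
    ``unstable_fraction`` injects a fraction of participants flagged as
    having unstable adaptive runs, to exercise the +/-5 dB screen.
    """

    n: int = 159
    age_range: tuple[float, float] = (18.0, 79.0)
    age_to_pta: float = 0.746
    age_to_afg: float = 0.244
    pta_to_afg: float = 0.373
    loading_fixed: float = 0.974
    loading_low: float = 0.708
    loading_high: float = 0.579
    afg_to_sin: float = 0.557
    pta_to_sin: float = 0.208
    age_to_sin: float = 0.339
    loading_win: float = 0.816
    loading_sib: float = 0.745
    age_to_win: float = 0.039
    dyn_residual_corr: float = 0.30
    ssq_sin_coupling: float = 0.0
    unstable_fraction: float = 0.06

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        paths = (self.age_to_pta, self.age_to_afg, self.pta_to_afg, self.afg_to_sin,
                 self.pta_to_sin, self.age_to_sin, self.loading_fixed, self.loading_low,
                 self.loading_high, self.loading_win, self.loading_sib, self.age_to_win)
        if any(abs(p) >= 1 for p in paths):
            raise ValueError("standardized paths must have |value| < 1")
        if not 0 <= self.unstable_fraction < 1:
            raise ValueError("unstable_fraction must be in [0, 1)")
        # residual variances must be positive given the path structure
        if min(self._residual_variances().values()) <= 0:
            raise ValueError("path coefficients imply a non-positive residual variance")

    # -- standardized-system algebra ------------------------------------

    def _corr_core(self) -> dict:
        """Pairwise correlations among the standardized system variables."""
        a = self.age_to_pta
        r_ag = self.age_to_afg + self.pta_to_afg * a
        r_pg = self.pta_to_afg + self.age_to_afg * a
        q1, q2, q3 = self.afg_to_sin, self.pta_to_sin, self.age_to_sin
        r_as = q1 * r_ag + q2 * a + q3
        r_ps = q1 * r_pg + q2 + q3 * a
        r_gs = q1 + q2 * r_pg + q3 * r_ag
        return dict(r_ap=a, r_ag=r_ag, r_pg=r_pg, r_as=r_as, r_ps=r_ps, r_gs=r_gs)

    def _residual_variances(self) -> dict:
        c = self._corr_core()
        a = self.age_to_pta
        g1, g2 = self.age_to_afg, self.pta_to_afg
        q = np.array([self.afg_to_sin, self.pta_to_sin, self.age_to_sin])
        cmat = np.array([[1, c["r_pg"], c["r_ag"]],
                         [c["r_pg"], 1, a],
                         [c["r_ag"], a, 1]])
        v = {
            "PTA": 1 - a**2,
            "AFG": 1 - (g1**2 + g2**2 + 2 * g1 * g2 * a),
            "SIN": 1 - float(q @ cmat @ q),
            "AFG_fixed": 1 - self.loading_fixed**2,
            "AFG_low": 1 - self.loading_low**2,
            "AFG_high": 1 - self.loading_high**2,
            "WiN": 1 - (self.loading_win**2 + self.age_to_win**2
                        + 2 * self.loading_win * self.age_to_win * c["r_as"]),
            "SiB": 1 - self.loading_sib**2,
        }
        return v


def cohort_defaults(n: int = 159) -> CohortParams:
    """The calibrated default parameter set (only the size is adjustable)."""
    return CohortParams(n=n)


def implied_correlations(params: CohortParams | None = None) -> pd.DataFrame:
    """Model-implied Pearson correlations of the seven analysis variables.

    WiN is oriented as recorded (proportion correct, higher = better), hence
    its negative correlations with the threshold-style scores.
    """
    p = params or cohort_defaults()
    c = p._corr_core()
    lam = {"AFG_fixed": p.loading_fixed, "AFG_low": p.loading_low, "AFG_high": p.loading_high}
    r = {}
    varnames = ["age", "PTA", "AFG_fixed", "AFG_low", "AFG_high", "WiN", "SiB"]

    def base(x: str) -> dict:
        """Correlations of variable x with the core A/P/G/S system."""
        if x == "age":
            return dict(A=1.0, P=c["r_ap"], G=c["r_ag"], S=c["r_as"])
        if x == "PTA":
            return dict(A=c["r_ap"], P=1.0, G=c["r_pg"], S=c["r_ps"])
        if x in lam:
            l = lam[x]
            return dict(A=l * c["r_ag"], P=l * c["r_pg"], G=l, S=l * c["r_gs"])
        if x == "SiB":
            l = p.loading_sib
            return dict(A=l * c["r_as"], P=l * c["r_ps"], G=l * c["r_gs"], S=l)
        if x == "WiN":  # worse-is-higher orientation before the sign flip
            lw, d = p.loading_win, p.age_to_win
            return dict(A=lw * c["r_as"] + d, P=lw * c["r_ps"] + d * c["r_ap"],
                        G=lw * c["r_gs"] + d * c["r_ag"], S=lw + d * c["r_as"])
        raise KeyError(x)

    def pair(x: str, y: str) -> float:
        bx, by = base(x), base(y)
        if y in ("age", "PTA"):
            x, y, bx, by = y, x, by, bx
        if x == "age":
            v = by["A"]
        elif x == "PTA":
            v = by["P"]
        elif x in lam and y in lam:
            v = lam[x] * by["G"]
            if {x, y} == {"AFG_low", "AFG_high"}:
                v += p.dyn_residual_corr * np.sqrt(
                    (1 - p.loading_low**2) * (1 - p.loading_high**2))
        elif x in lam:
            v = lam[x] * by["G"]
        elif y in lam:
            v = lam[y] * base(x)["G"]
        else:  # WiN-SiB
            v = p.loading_sib * base("WiN")["S"]
        return float(v)

    mat = pd.DataFrame(np.eye(len(varnames)), index=varnames, columns=varnames)
    for x, y in combinations(varnames, 2):
        v = pair(x, y)
        if "WiN" in (x, y):
            v = -v  # recorded WiN is proportion correct
        mat.loc[x, y] = mat.loc[y, x] = v
    return mat


def implied_spearman(params: CohortParams | None = None) -> pd.DataFrame:
    """Model-implied Spearman correlations (Gaussian copula transform).

    Exact for this generator: every recorded score is a monotone transform
    of a jointly Gaussian system, so rho_S = (6/pi) * asin(rho_P / 2).
    """
    r = implied_correlations(params)
    out = 6 / np.pi * np.arcsin(r / 2)
    np.fill_diagonal(out.values, 1.0)
    return out


def simulate_cohort(params: CohortParams | None = None, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a participant table from the latent-variable system.

    Returns a DataFrame with columns ``age, PTA, AFG_fixed, AFG_low,
    AFG_high, WiN, SiB, SSQ`` on their natural scales plus a boolean
    ``stable`` column (False for the injected fraction of participants whose
    adaptive runs would fail the +/-5 dB stability screen).
    """
    p = params or cohort_defaults()
    rng = rng or np.random.default_rng()
    n = p.n
    v = p._residual_variances()

    z_age = rng.standard_normal(n)
    z_pta = p.age_to_pta * z_age + np.sqrt(v["PTA"]) * rng.standard_normal(n)
    z_afg = (p.age_to_afg * z_age + p.pta_to_afg * z_pta
             + np.sqrt(v["AFG"]) * rng.standard_normal(n))

    # shared residual between the two dynamic tasks ("they covary")
    rho = p.dyn_residual_corr
    e_shared = rng.standard_normal(n)
    e_low = np.sqrt(rho) * e_shared + np.sqrt(1 - rho) * rng.standard_normal(n)
    e_high = np.sqrt(rho) * e_shared + np.sqrt(1 - rho) * rng.standard_normal(n)
    z_fixed = p.loading_fixed * z_afg + np.sqrt(v["AFG_fixed"]) * rng.standard_normal(n)
    z_low = p.loading_low * z_afg + np.sqrt(v["AFG_low"]) * e_low
    z_high = p.loading_high * z_afg + np.sqrt(v["AFG_high"]) * e_high

    z_sin = (p.afg_to_sin * z_afg + p.pta_to_sin * z_pta + p.age_to_sin * z_age
             + np.sqrt(v["SIN"]) * rng.standard_normal(n))
    z_win_worse = (p.loading_win * z_sin + p.age_to_win * z_age
                   + np.sqrt(v["WiN"]) * rng.standard_normal(n))
    z_sib = p.loading_sib * z_sin + np.sqrt(v["SiB"]) * rng.standard_normal(n)

    lo, hi = p.age_range
    age = lo + (hi - lo) * ndtr(z_age)  # uniform over the age range
    win = 1.0 / (1.0 + np.exp(-(_WIN_ALPHA - _WIN_BETA * z_win_worse)))
    ssq_core = p.ssq_sin_coupling * z_sin + np.sqrt(1 - p.ssq_sin_coupling**2) * rng.standard_normal(n)
    ssq = np.clip(5.0 + 2.0 * ssq_core, 0.0, 10.0)

    df = pd.DataFrame({
        "age": age,
        "PTA": SCALE["PTA"][0] + SCALE["PTA"][1] * z_pta,
        "AFG_fixed": SCALE["AFG_fixed"][0] + SCALE["AFG_fixed"][1] * z_fixed,
        "AFG_low": SCALE["AFG_low"][0] + SCALE["AFG_low"][1] * z_low,
        "AFG_high": SCALE["AFG_high"][0] + SCALE["AFG_high"][1] * z_high,
        "WiN": win,
        "SiB": SCALE["SiB"][0] + SCALE["SiB"][1] * z_sib,
        "SSQ": ssq,
    })
    df["stable"] = rng.random(n) >= p.unstable_fraction
    return df
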
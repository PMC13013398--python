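"""Hierarchical one-step reaction norm model fit by Gibbs sampling.

The observation model for animal i with record in contemporary group j is

    y_ij = x_i' beta + l_j + a_i + b_i * l_j + pm_{dam(i)} + e_ij

with beta the fixed effects (intercept, cow-age linear and quadratic; age is
centred at its sample mean), l_j ~ N(0, sigma2_cg) the random
contemporary-group environmental effect, (a, b) the intercept/slope breeding
values with prior N(0, G x A) structured by the numerator relationship
matrix, pm a maternal permanent environment effect per dam, and Gaussian
residuals.  The current draw of l_j is the environmental covariate of the
slope, so the gradient and the reaction norms are estimated jointly in one
step rather than from pre-estimated CG solutions.

Priors: flat on beta, inverse-Wishart (4 df, diagonal scale at a quarter of
the phenotypic variance) on G, scaled inverse chi-square (4 df, scale a
quarter of the phenotypic variance) on the scalar variances.  These are
proper but diffuse; with thousands of records they contribute negligibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _gibbs
from .data_prep import PhenotypeRecord
from .params import GeneticCovariance
from .pedigree import Pedigree, build_a_inverse

BETA_NAMES = ("intercept", "age_linear", "age_quadratic")


class ModelError(ValueError):
    pass


@dataclass
class Priors:
    """Hyperparameters; ``None`` scales are resolved from the data as
    0.25 x the sample phenotypic variance."""

    nu_g: float = 4.0
    g_scale_intercept: Optional[float] = None
    g_scale_slope: Optional[float] = None
    g_scale_cross: float = 0.0
    nu_scalar: float = 4.0
    cg_scale: Optional[float] = None
    pe_scale: Optional[float] = None
    e_scale: Optional[float] = None

    def resolved(self, var_y: float) -> "Priors":
        base = 0.25 * var_y
        return Priors(
            nu_g=self.nu_g,
            g_scale_intercept=base if self.g_scale_intercept is None else self.g_scale_intercept,
            g_scale_slope=base if self.g_scale_slope is None else self.g_scale_slope,
            g_scale_cross=self.g_scale_cross,
            nu_scalar=self.nu_scalar,
            cg_scale=base if self.cg_scale is None else self.cg_scale,
            pe_scale=base if self.pe_scale is None else self.pe_scale,
            e_scale=base if self.e_scale is None else self.e_scale,
        )


@dataclass
class ModelConfig:
    """Chain settings; defaults mirror the full-length analysis profile."""

    n_iterations: int = 200_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 1
    priors: Priors = field(default_factory=Priors)
    freeze_slopes: bool = False  # diagnostic mode: reduces to a standard animal model
    center_cg_effects: bool = False
    update_order: str = "default"  # or "alternate" (location blocks permuted)

    def validate(self) -> None:
        if self.thin < 1:
            raise ModelError("thin must be >= 1")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ModelError("require 0 <= burn_in < n_iterations")
        if (self.n_iterations - self.burn_in) // self.thin < 1:
            raise ModelError("chain settings leave no saved draws")
        if self.update_order not in ("default", "alternate"):
            raise ModelError(f"unknown update_order {self.update_order!r}")

    @property
    def n_saved(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws of all model parameters.

    Location draws (``a``, ``b``, ``pm``, ``cg``) may be ``None`` when the
    object was reloaded from a means-only save; their posterior means are
    always available.
    """

    beta: np.ndarray              # (S, 3)
    cg: Optional[np.ndarray]      # (S, n_cg)
    a: Optional[np.ndarray]       # (S, q)
    b: Optional[np.ndarray]
    pm: Optional[np.ndarray]
    G: np.ndarray                 # (S, 3): sigma2_i, sigma2_l, sigma_il
    sigma2_cg: np.ndarray
    sigma2_pe: np.ndarray
    sigma2_e: np.ndarray
    animal_ids: list
    cg_ids: list
    dam_ids: list
    cg_mean: np.ndarray = None
    a_mean: np.ndarray = None
    b_mean: np.ndarray = None
    pm_mean: np.ndarray = None

    def __post_init__(self):
        if self.cg_mean is None and self.cg is not None:
            self.cg_mean = self.cg.mean(axis=0)
        if self.a_mean is None and self.a is not None:
            self.a_mean = self.a.mean(axis=0)
        if self.b_mean is None and self.b is not None:
            self.b_mean = self.b.mean(axis=0)
        if self.pm_mean is None and self.pm is not None:
            self.pm_mean = self.pm.mean(axis=0)

    @property
    def n_draws(self) -> int:
        return self.G.shape[0]

    def genetic_covariance_mean(self) -> GeneticCovariance:
        m = self.G.mean(axis=0)
        return GeneticCovariance(m[0], m[1], m[2])

    def dispersion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sigma2_i": self.G[:, 0],
                "sigma2_l": self.G[:, 1],
                "sigma_il": self.G[:, 2],
                "sigma2_cg": self.sigma2_cg,
                "sigma2_pe": self.sigma2_pe,
                "sigma2_e": self.sigma2_e,
            }
        )

    def cg_solutions(self) -> dict:
        return {c: float(v) for c, v in zip(self.cg_ids, self.cg_mean)}

    def slope_means(self) -> dict:
        return {a: float(v) for a, v in zip(self.animal_ids, self.b_mean)}

    def intercept_means(self) -> dict:
        return {a: float(v) for a, v in zip(self.animal_ids, self.a_mean)}

    def credible_interval(self, chain: np.ndarray, level: float = 0.95):
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(chain, [lo, 1.0 - lo]))

    def save(self, out_dir) -> None:
        """Write dispersion/beta draws in full and location posterior means.

        Layout: ``dispersion.csv`` (one row per saved draw), ``beta.csv``,
        ``cg_effects.csv`` (cg, mean), ``breeding_values.csv`` (animal,
        intercept_mean, slope_mean), ``pm_effects.csv`` (dam, mean) and
        ``draws_meta.json``.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.dispersion_frame().to_csv(out_dir / "dispersion.csv", index=False)
        pd.DataFrame(self.beta, columns=list(BETA_NAMES)).to_csv(
            out_dir / "beta.csv", index=False
        )
        pd.DataFrame({"cg": self.cg_ids, "mean": self.cg_mean}).to_csv(
            out_dir / "cg_effects.csv", index=False
        )
        pd.DataFrame(
            {
                "animal": self.animal_ids,
                "intercept_mean": self.a_mean,
                "slope_mean": self.b_mean,
            }
        ).to_csv(out_dir / "breeding_values.csv", index=False)
        pd.DataFrame({"dam": self.dam_ids, "mean": self.pm_mean}).to_csv(
            out_dir / "pm_effects.csv", index=False
        )
        meta = {
            "n_draws": int(self.n_draws),
            "n_animals": len(self.animal_ids),
            "n_cgs": len(self.cg_ids),
            "n_dams": len(self.dam_ids),
        }
        (out_dir / "draws_meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, out_dir) -> "PosteriorSamples":
        out_dir = Path(out_dir)
        disp = pd.read_csv(out_dir / "dispersion.csv")
        beta = pd.read_csv(out_dir / "beta.csv").to_numpy()
        cg = pd.read_csv(out_dir / "cg_effects.csv")
        bv = pd.read_csv(out_dir / "breeding_values.csv")
        pmf = pd.read_csv(out_dir / "pm_effects.csv")
        return cls(
            beta=beta,
            cg=None,
            a=None,
            b=None,
            pm=None,
            G=disp[["sigma2_i", "sigma2_l", "sigma_il"]].to_numpy(),
            sigma2_cg=disp["sigma2_cg"].to_numpy(),
            sigma2_pe=disp["sigma2_pe"].to_numpy(),
            sigma2_e=disp["sigma2_e"].to_numpy(),
            animal_ids=bv["animal"].tolist(),
            cg_ids=cg["cg"].tolist(),
            dam_ids=pmf["dam"].tolist(),
            cg_mean=cg["mean"].to_numpy(),
            a_mean=bv["intercept_mean"].to_numpy(),
            b_mean=bv["slope_mean"].to_numpy(),
            pm_mean=pmf["mean"].to_numpy(),
        )


def fit(
    records: Sequence[PhenotypeRecord],
    pedigree: Pedigree,
    config: ModelConfig,
    initial_state: Optional[dict] = None,
) -> PosteriorSamples:
    """Run the Gibbs sampler and return the saved posterior draws.

    ``initial_state`` may supply starting values for any of ``cg`` (array in
    sorted-CG order), ``a``, ``b`` (pedigree order), ``pm`` (dam order) and
    the dispersion parameters ``sigma2_i, sigma2_l, sigma_il, sigma2_cg,
    sigma2_pe, sigma2_e``; everything else starts at zero / the prior scale.
    """
    config.validate()
    if len(records) == 0:
        raise ModelError("no phenotype records")
    for r in records:
        if r.animal not in pedigree.id_index:
            raise ModelError(f"record animal {r.animal!r} is not in the pedigree")

    cg_ids = sorted({r.cg for r in records}, key=str)
    if len(cg_ids) < 2:
        raise ModelError("need at least 2 contemporary groups")
    cg_index = {c: j for j, c in enumerate(cg_ids)}

    n = len(records)
    q = pedigree.n
    y = np.array([r.value for r in records], dtype=float)
    ages = np.array([r.cow_age for r in records], dtype=float)
    age_c = ages - ages.mean()
    X = np.column_stack([np.ones(n), age_c, age_c**2])

    rec_an = np.array([pedigree.id_index[r.animal] for r in records], dtype=np.int64)
    rec_cg = np.array([cg_index[r.cg] for r in records], dtype=np.int64)

    dam_idx_of_rec = np.array(
        [pedigree.id_index.get(r.dam, -1) if r.dam is not None else -1 for r in records],
        dtype=np.int64,
    )
    dam_ids_idx = sorted(set(dam_idx_of_rec[dam_idx_of_rec >= 0].tolist()))
    dam_pos = {d: j for j, d in enumerate(dam_ids_idx)}
    rec_pm = np.array(
        [dam_pos[d] if d >= 0 else -1 for d in dam_idx_of_rec], dtype=np.int64
    )
    dam_ids = [pedigree.ids[d] for d in dam_ids_idx]

    def group(keys: np.ndarray, n_groups: int):
        order = np.argsort(keys, kind="stable")
        keys_sorted = keys[order]
        ptr = np.searchsorted(keys_sorted, np.arange(n_groups + 1))
        return ptr.astype(np.int64), order.astype(np.int64)

    cg_ptr, cg_rec = group(rec_cg, len(cg_ids))
    an_ptr, an_rec = group(rec_an, q)
    valid_pm = rec_pm >= 0
    if valid_pm.any():
        order = np.argsort(rec_pm[valid_pm], kind="stable")
        pm_rec = np.flatnonzero(valid_pm)[order].astype(np.int64)
        pm_sorted = rec_pm[pm_rec]
        pm_ptr = np.searchsorted(pm_sorted, np.arange(len(dam_ids_idx) + 1)).astype(np.int64)
    else:
        pm_rec = np.zeros(0, dtype=np.int64)
        pm_ptr = np.zeros(1, dtype=np.int64)

    ai = build_a_inverse(pedigree).tocsr()
    ai_diag = ai.diagonal().astype(float)

    var_y = float(np.var(y, ddof=1)) if n > 1 else 1.0
    pr = config.priors.resolved(var_y)

    beta_init, *_ = np.linalg.lstsq(X, y, rcond=None)

    state = initial_state or {}
    init_lcg = np.asarray(state.get("cg", np.zeros(len(cg_ids))), dtype=float)
    init_a = np.asarray(state.get("a", np.zeros(q)), dtype=float)
    init_b = np.asarray(state.get("b", np.zeros(q)), dtype=float)
    init_pm = np.asarray(state.get("pm", np.zeros(max(len(dam_ids), 0))), dtype=float)
    init_disp = np.array(
        [
            state.get("sigma2_i", pr.g_scale_intercept),
            state.get("sigma2_l", pr.g_scale_slope),
            state.get("sigma_il", 0.0),
            state.get("sigma2_cg", pr.cg_scale),
            state.get("sigma2_pe", pr.pe_scale),
            state.get("sigma2_e", pr.e_scale),
        ],
        dtype=float,
    )

    S = config.n_saved
    out_beta = np.empty((S, 3))
    out_cg = np.empty((S, len(cg_ids)))
    out_a = np.empty((S, q))
    out_b = np.empty((S, q))
    out_pm = np.empty((S, max(len(dam_ids), 0)))
    out_G = np.empty((S, 3))
    out_s2cg = np.empty(S)
    out_s2pe = np.empty(S)
    out_s2e = np.empty(S)

    status = _gibbs.run_chain(
        y, X, rec_an, rec_cg, rec_pm,
        cg_ptr, cg_rec, an_ptr, an_rec, pm_ptr, pm_rec,
        ai.indptr.astype(np.int64), ai.indices.astype(np.int64),
        ai.data.astype(float), ai_diag,
        beta_init, init_lcg, init_a, init_b, init_pm, init_disp,
        float(pr.nu_g), float(pr.g_scale_intercept), float(pr.g_scale_slope),
        float(pr.g_scale_cross),
        float(pr.nu_scalar), float(pr.cg_scale),
        float(pr.nu_scalar), float(pr.pe_scale),
        float(pr.nu_scalar), float(pr.e_scale),
        int(config.n_iterations), int(config.burn_in), int(config.thin),
        int(config.seed) & 0x7FFFFFFF,
        bool(config.freeze_slopes), bool(config.center_cg_effects),
        0 if config.update_order == "default" else 1,
        out_beta, out_cg, out_a, out_b, out_pm,
        out_G, out_s2cg, out_s2pe, out_s2e,
    )
    if status != _gibbs.STATUS_OK:
        raise ModelError(
            f"numerical failure in a conditional draw at iteration {status % 1000000}"
        )
    return PosteriorSamples(
        beta=out_beta, cg=out_cg, a=out_a, b=out_b, pm=out_pm,
        G=out_G, sigma2_cg=out_s2cg, sigma2_pe=out_s2pe, sigma2_e=out_s2e,
        animal_ids=list(pedigree.ids), cg_ids=cg_ids, dam_ids=dam_ids,
    )


# ---------------------------------------------------------------------------
# Geweke convergence diagnostic


@dataclass(frozen=True)
class GewekeResult:
    z: float           # nan when degenerate
    degenerate: bool
    flagged: bool      # |z| exceeds the two-sided critical value
    first_frac: float
    last_frac: float


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-windowed
    autocovariance sum (Newey-West lag ``4*(m/100)**(2/9)``)."""
    m = len(x)
    xc = x - x.mean()
    lag = int(np.floor(4.0 * (m / 100.0) ** (2.0 / 9.0)))
    lag = min(lag, m - 1)
    g0 = float(xc @ xc) / m
    s = g0
    for k in range(1, lag + 1):
        gk = float(xc[k:] @ xc[:-k]) / m
        s += 2.0 * (1.0 - k / (lag + 1.0)) * gk
    return max(s, 0.0)


def geweke_diagnostic(
    chain,
    first_frac: float = 0.1,
    last_frac: float = 0.5,
    alpha: float = 0.05,
) -> GewekeResult:
    """Compare early- and late-chain means with spectral standard errors.

    ``z = (mean_first - mean_last) / sqrt(S_f(0)/n_f + S_l(0)/n_l)``; the
    two-sided test at ``alpha`` flags ``|z|`` beyond the normal critical
    value.  A zero-variance (constant) chain is reported as degenerate
    rather than producing a division by zero.
    """
    x = np.asarray(chain, dtype=float)
    if x.ndim != 1 or len(x) < 100:
        raise ValueError("chain must be one-dimensional with length >= 100")
    if not (0 < first_frac and 0 < last_frac and first_frac + last_frac <= 1):
        raise ValueError("require first_frac > 0, last_frac > 0 and sum <= 1")
    n = len(x)
    xa = x[: max(int(first_frac * n), 2)]
    xb = x[n - max(int(last_frac * n), 2):]
    var = np.sqrt(_spectral_density_zero(xa) / len(xa) + _spectral_density_zero(xb) / len(xb))
    if var == 0.0 or not np.isfinite(var):
        return GewekeResult(np.nan, True, False, first_frac, last_frac)
    z = float((xa.mean() - xb.mean()) / var)
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return GewekeResult(z, False, bool(abs(z) > crit), first_frac, last_frac)


def geweke_table(samples: PosteriorSamples, **kwargs) -> pd.DataFrame:
    """Geweke z-scores for every dispersion-parameter chain."""
    frame = samples.dispersion_frame()
    rows = []
    for name in frame.columns:
        res = geweke_diagnostic(frame[name].to_numpy(), **kwargs)
        rows.append(
            {"parameter": name, "z": res.z, "degenerate": res.degenerate, "flagged": res.flagged}
        )
    return pd.DataFrame(rows)
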
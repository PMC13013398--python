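"""Environmental gradients, per-gradient genetic parameters and correlations.

Contemporary groups are ranked by their posterior-mean environmental effects
and cut into k quantile levels (default five, each nominally 20% of the
distribution, level 1 the poorest environments and level k the best).  The
environmental descriptor X of a level is the mean of its member CG
solutions.  Along the gradient the additive genetic variance follows the
covariance function

    sigma2_a(X) = sigma2_i + X**2 * sigma2_l + 2 * X * sigma_il

and the genetic covariance between two environments Xx, Xy is
``sigma2_i + (Xx + Xy) * sigma_il + Xx * Xy * sigma2_l``.  Heritabilities
and correlations are evaluated draw-wise over the chain and reported as
posterior mean and SD.  The heritability denominator is
``sigma2_a(X) + sigma2_pe + sigma2_e`` — the gradient itself is treated as
environment, not noise — with an option to add ``sigma2_cg``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import GeneticCovariance
from .rn_model import PosteriorSamples

_CLIP_TOL = 1e-12


class SummaryError(ValueError):
    pass


@dataclass
class GradientLevel:
    level: int           # 1-based, ascending environment
    X: float             # mean posterior CG solution of the level
    member_cgs: set

    @property
    def n_cgs(self) -> int:
        return len(self.member_cgs)


def assign_gradients(cg_solutions: Mapping, k: int = 5) -> list:
    """Cut CGs into k ascending quantile levels of near-equal CG counts.

    Sizes follow the largest-remainder rule (extra CGs go to the lowest
    levels); ties in the solutions are broken by CG id for determinism.
    """
    if k < 2:
        raise SummaryError("k must be >= 2")
    items = sorted(cg_solutions.items(), key=lambda kv: (kv[1], str(kv[0])))
    n = len(items)
    if n < k:
        raise SummaryError(f"only {n} CGs for k={k} gradient levels")
    base, rem = divmod(n, k)
    sizes = [base + 1 if i < rem else base for i in range(k)]
    levels = []
    start = 0
    for i, sz in enumerate(sizes, start=1):
        chunk = items[start : start + sz]
        start += sz
        levels.append(
            GradientLevel(
                level=i,
                X=float(np.mean([v for _, v in chunk])),
                member_cgs={c for c, _ in chunk},
            )
        )
    return levels


def additive_variance_at(X: float, G: GeneticCovariance) -> float:
    """sigma2_a(X) = sigma2_i + X^2 sigma2_l + 2 X sigma_il (>= 0 for PSD G)."""
    return float(G.sigma2_i + X * X * G.sigma2_l + 2.0 * X * G.sigma_il)


def genetic_correlation(Xx: float, Xy: float, G: GeneticCovariance) -> float:
    """Correlation of breeding values expressed at environments Xx and Xy.

    Returns exactly 1 for identical environments and for a no-G-by-E matrix
    (sigma2_l = sigma_il = 0); raises on a zero variance at either level.
    Values are clipped to [-1, 1] only against floating-point overshoot.
    """
    vx = additive_variance_at(Xx, G)
    vy = additive_variance_at(Xy, G)
    if vx <= 0.0 or vy <= 0.0:
        raise SummaryError(
            f"degenerate: zero additive variance at X={Xx if vx <= 0 else Xy}"
        )
    cov = G.sigma2_i + (Xx + Xy) * G.sigma_il + Xx * Xy * G.sigma2_l
    r = cov / np.sqrt(vx * vy)
    # PSD G cannot give |r| > 1 beyond floating-point overshoot
    if 1.0 < abs(r) <= 1.0 + _CLIP_TOL * max(1.0, abs(r)):
        r = np.sign(r)
    return float(min(1.0, max(-1.0, r)))


def heritability_at(
    level: GradientLevel,
    draws: PosteriorSamples,
    include_cg: bool = False,
) -> tuple:
    """Posterior mean and SD of h2 at the level's X, evaluated draw-wise."""
    if draws.n_draws == 0:
        raise SummaryError("no posterior draws")
    X = level.X
    va = draws.G[:, 0] + X * X * draws.G[:, 1] + 2.0 * X * draws.G[:, 2]
    denom = va + draws.sigma2_pe + draws.sigma2_e
    if include_cg:
        denom = denom + draws.sigma2_cg
    h2 = va / denom
    return float(h2.mean()), float(h2.std(ddof=0))


@dataclass
class GradientSummary:
    levels: list
    sigma2_a: dict       # level -> (posterior mean, SD)
    h2: dict             # level -> (posterior mean, SD)
    r_g: np.ndarray      # (k, k) posterior-mean genetic correlations

    def frame(self) -> pd.DataFrame:
        rows = []
        for lv in self.levels:
            va_m, va_s = self.sigma2_a[lv.level]
            h2_m, h2_s = self.h2[lv.level]
            rows.append(
                {
                    "level": lv.level,
                    "X": lv.X,
                    "n_cgs": lv.n_cgs,
                    "sigma2_a_mean": va_m,
                    "sigma2_a_sd": va_s,
                    "h2_mean": h2_m,
                    "h2_sd": h2_s,
                }
            )
        return pd.DataFrame(rows)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.frame().to_csv(out_dir / "gradient_summary.csv", index=False)
        k = len(self.levels)
        pd.DataFrame(
            self.r_g,
            index=[f"level{i + 1}" for i in range(k)],
            columns=[f"level{i + 1}" for i in range(k)],
        ).to_csv(out_dir / "genetic_correlations.csv")

    def plot_correlations(self, path) -> None:
        """Heatmap of between-level genetic correlations."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        k = len(self.levels)
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(self.r_g, vmin=-1, vmax=1, cmap="viridis", origin="lower")
        ax.set_xticks(range(k), [str(i + 1) for i in range(k)])
        ax.set_yticks(range(k), [str(i + 1) for i in range(k)])
        ax.set_xlabel("environmental gradient")
        ax.set_ylabel("environmental gradient")
        for i in range(k):
            for j in range(k):
                ax.text(j, i, f"{self.r_g[i, j]:.2f}", ha="center", va="center", fontsize=7)
        fig.colorbar(im, ax=ax, label="genetic correlation")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def summarize(
    draws: PosteriorSamples,
    k: int = 5,
    include_cg_in_h2: bool = False,
) -> GradientSummary:
    """Gradient levels plus draw-wise per-level variances, h2 and correlations."""
    levels = assign_gradients(draws.cg_solutions(), k=k)
    sigma2_a = {}
    h2 = {}
    for lv in levels:
        X = lv.X
        va = draws.G[:, 0] + X * X * draws.G[:, 1] + 2.0 * X * draws.G[:, 2]
        sigma2_a[lv.level] = (float(va.mean()), float(va.std(ddof=0)))
        h2[lv.level] = heritability_at(lv, draws, include_cg=include_cg_in_h2)
    r_g = np.eye(k)
    Xs = [lv.X for lv in levels]
    for i in range(k):
        for j in range(i + 1, k):
            vx = draws.G[:, 0] + Xs[i] ** 2 * draws.G[:, 1] + 2.0 * Xs[i] * draws.G[:, 2]
            vy = draws.G[:, 0] + Xs[j] ** 2 * draws.G[:, 1] + 2.0 * Xs[j] * draws.G[:, 2]
            cov = draws.G[:, 0] + (Xs[i] + Xs[j]) * draws.G[:, 2] + Xs[i] * Xs[j] * draws.G[:, 1]
            ok = (vx > 0) & (vy > 0)
            if not ok.any():
                raise SummaryError(f"zero additive variance in every draw between levels {i+1},{j+1}")
            r = np.clip(cov[ok] / np.sqrt(vx[ok] * vy[ok]), -1.0, 1.0)
            r_g[i, j] = r_g[j, i] = float(r.mean())
    return GradientSummary(levels=levels, sigma2_a=sigma2_a, h2=h2, r_g=r_g)
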
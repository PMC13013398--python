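"""Pedigreed population and phenotype simulator with known true parameters.

The generator emulates a multi-herd, Nellore-like beef cattle population:
discrete generations under random mating (a subset of males serves as sires
and a subset of females as dams, so half/full-sib families arise naturally),
contemporary groups nested within generation and sex (the field definition of
a CG — herd, year, season, sex — collapses here to an exchangeable grouping
with its own variance), a cow-age-at-calving covariate with linear and
quadratic effects, correlated intercept/slope breeding values structured by
the numerator relationship matrix, maternal permanent environment effects
keyed by dam, and Gaussian residuals.

Every downstream stage of the package has a parameter-recovery test surface
against the returned :class:`TruthBundle`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy import stats

from .data_prep import PhenotypeRecord, write_phenotypes
from .params import GeneticCovariance
from .pedigree import Pedigree, inbreeding_array, mendelian_variance, write_pedigree


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generative parameters; defaults give ~2,000 phenotyped animals in 100 CGs.

    ``beta_age`` applies to cow age centred at ``age_mean_sd[0]``; ages are
    drawn truncated-normal with the stated moments and a floor of ``min_age``
    months (a cow younger than two years cannot have calved).
    """

    n_founders: int = 500
    n_generations: int = 5
    n_cgs: int = 100
    cg_size_distribution: float = 20.0  # mean records per CG (used when n_cgs=0)
    true_G: GeneticCovariance = field(
        default_factory=lambda: GeneticCovariance(100.0, 25.0, 20.0)
    )
    sigma2_cg: float = 150.0
    sigma2_pe: float = 30.0
    sigma2_e: float = 200.0
    beta_age: tuple = (0.3, -0.002)
    age_mean_sd: tuple = (72.63, 36.65)
    seed: int = 1
    mu: float = 0.0
    sire_fraction: float = 0.03  # share of eligible males used as sires; gives ~30 progeny/sire at default scale, matching herd-book records-per-sire ratios
    dam_fraction: float = 0.5
    min_age: float = 24.0

    def __post_init__(self):
        if not isinstance(self.true_G, GeneticCovariance):
            self.true_G = GeneticCovariance(*self.true_G)
        if self.n_founders < 2:
            raise SimulationError("n_founders must be >= 2 to form matings")
        if self.n_generations < 0 or self.n_cgs < 0:
            raise SimulationError("counts must be non-negative")
        for name in ("sigma2_cg", "sigma2_pe", "sigma2_e"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.age_mean_sd[1] < 0:
            raise SimulationError("age SD must be >= 0")


@dataclass
class TruthBundle:
    """True simulated effects, keyed by the ids used in the output files."""

    true_intercepts: dict
    true_slopes: dict
    true_cg_effects: dict
    true_pe_effects: dict

    def write_csv(self, out_dir) -> None:
        out_dir = Path(out_dir)
        with open(out_dir / "truth_animals.csv", "w") as fh:
            fh.write("animal,intercept,slope\n")
            for a in self.true_intercepts:
                fh.write(f"{a},{self.true_intercepts[a]:.10g},{self.true_slopes[a]:.10g}\n")
        with open(out_dir / "truth_cgs.csv", "w") as fh:
            fh.write("cg,effect\n")
            for c, v in self.true_cg_effects.items():
                fh.write(f"{c},{v:.10g}\n")
        with open(out_dir / "truth_pe.csv", "w") as fh:
            fh.write("dam,effect\n")
            for d, v in self.true_pe_effects.items():
                fh.write(f"{d},{v:.10g}\n")


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Overlapping-generation random-mating pedigree, one progeny per mating.

    Founders have unknown parents.  Each subsequent generation (one
    birth-year cohort of ``n_founders`` calves) is produced by a breeding
    herd: a sampled pool of sires (active for up to three cohorts) and a
    breeding-cow pool (active for up to four cohorts) in which every dam
    calves at most once per cohort — a cow cannot have two calves in the
    same herd-year-season.  A dam's progeny are therefore spread across
    cohorts, as in real herd records.  Output order is topological by
    construction.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    n0 = config.n_founders
    sex_male = list(rng.random(n0) < 0.5)
    # guarantee both sexes among founders so matings exist
    if config.n_generations >= 1:
        if not any(sex_male):
            sex_male[0] = True
        if all(sex_male):
            sex_male[0] = False
    triples = [(i + 1, 0, 0) for i in range(n0)]
    cohorts = [list(range(n0))]
    next_id = n0 + 1
    sire_life, dam_life = 3, 4
    for _ in range(config.n_generations):
        cand_m = [i for c in cohorts[-sire_life:] for i in c if sex_male[i]]
        cand_f = [i for c in cohorts[-dam_life:] for i in c if not sex_male[i]]
        n_sires = min(len(cand_m), max(2, round(config.sire_fraction * len(cand_m))))
        sire_pool = rng.choice(cand_m, size=n_sires, replace=False)
        n_dams = min(len(cand_f), max(2, round(config.dam_fraction * len(cand_f))))
        if n_dams < n0:
            n_dams = min(len(cand_f), n0)  # need one distinct dam per calf
        dam_pool = rng.choice(cand_f, size=n_dams, replace=False)
        n_off = min(n0, n_dams)
        dams = rng.choice(dam_pool, size=n_off, replace=False)  # <= 1 calf/dam/cohort
        sires = sire_pool[rng.integers(0, n_sires, size=n_off)]
        off_sex = rng.random(n_off) < 0.5
        cur = []
        for k in range(n_off):
            triples.append((next_id, int(sires[k]) + 1, int(dams[k]) + 1))
            cur.append(next_id - 1)
            sex_male.append(bool(off_sex[k]))
            next_id += 1
        cohorts.append(cur)
    return Pedigree.from_records(triples)


def _generations(ped: Pedigree) -> np.ndarray:
    gen = np.zeros(ped.n, dtype=np.int64)
    for i in range(ped.n):
        g = -1
        if ped.sire_idx[i] >= 0:
            g = max(g, gen[ped.sire_idx[i]])
        if ped.dam_idx[i] >= 0:
            g = max(g, gen[ped.dam_idx[i]])
        gen[i] = g + 1
    return gen


def _infer_sex(ped: Pedigree, rng: np.random.Generator) -> np.ndarray:
    """True = male.  Parents get the sex their role implies; the rest are coin flips."""
    male = np.zeros(ped.n, dtype=bool)
    is_sire = np.zeros(ped.n, dtype=bool)
    is_dam = np.zeros(ped.n, dtype=bool)
    is_sire[ped.sire_idx[ped.sire_idx >= 0]] = True
    is_dam[ped.dam_idx[ped.dam_idx >= 0]] = True
    male[is_sire] = True
    free = ~(is_sire | is_dam)
    male[free] = rng.random(int(free.sum())) < 0.5
    return male


def _largest_remainder(weights: np.ndarray, total: int, min_one: bool = True) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    quota = total * w / w.sum()
    out = np.floor(quota).astype(np.int64)
    rem = total - int(out.sum())
    order = np.argsort(-(quota - out), kind="stable")
    out[order[:rem]] += 1
    if min_one:
        while (out == 0).any() and (out > 1).any():
            out[np.argmax(out == 0)] += 1
            out[np.argmax(out)] -= 1
    return out


def simulate_breeding_values(
    ped: Pedigree, G: GeneticCovariance, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2) intercept/slope breeding values with covariance G x A.

    Founders are independent with covariance G; descendants follow the
    recursive parental-average plus Mendelian-sampling construction, the
    sampling covariance being G scaled by the inbreeding-adjusted share
    d_i = 1/2 * (1 - (F_s + F_d)/2) (with the usual unknown-parent variants).
    """
    L = G.sqrt_factor()
    F = inbreeding_array(ped)
    d = mendelian_variance(ped, F)
    Z = rng.standard_normal((ped.n, 2))
    ms = Z @ L.T * np.sqrt(d)[:, None]
    u = np.zeros((ped.n, 2))
    s_idx, d_idx = ped.sire_idx, ped.dam_idx
    for i in range(ped.n):
        mean0 = 0.0
        mean1 = 0.0
        if s_idx[i] >= 0:
            mean0 += 0.5 * u[s_idx[i], 0]
            mean1 += 0.5 * u[s_idx[i], 1]
        if d_idx[i] >= 0:
            mean0 += 0.5 * u[d_idx[i], 0]
            mean1 += 0.5 * u[d_idx[i], 1]
        u[i, 0] = mean0 + ms[i, 0]
        u[i, 1] = mean1 + ms[i, 1]
    return u


def simulate_phenotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[list, TruthBundle]:
    """Phenotype records plus the true effects that generated them.

    Record values decompose exactly as
    ``mu + beta_age . (age - mean, (age - mean)^2) + a_i + (1 + b_i) * cg_effect
    + pm(dam) + residual``; founders (phenotyped only when the pedigree has a
    single generation) carry no maternal permanent environment term.
    """
    cfg = config
    rng = np.random.default_rng([int(cfg.seed), 1])
    u = simulate_breeding_values(pedigree, cfg.true_G, rng)
    gen = _generations(pedigree)
    male = _infer_sex(pedigree, rng)

    if gen.max() >= 1:
        pheno = np.flatnonzero(gen >= 1)
    else:
        pheno = np.arange(pedigree.n)
    n_ph = len(pheno)
    n_cgs = cfg.n_cgs
    if n_cgs == 0:
        n_cgs = max(1, round(n_ph / cfg.cg_size_distribution))
    if n_cgs > n_ph:
        raise SimulationError(f"{n_cgs} CGs requested for {n_ph} phenotyped animals")

    # CGs nested within (generation, sex) cells; counts by largest remainder
    cells: dict = {}
    for i in pheno:
        cells.setdefault((int(gen[i]), bool(male[i])), []).append(int(i))
    keys = sorted(cells)
    cell_sizes = np.array([len(cells[k]) for k in keys])
    cgs_per_cell = _largest_remainder(cell_sizes, n_cgs)
    cg_of: dict = {}
    cg_ids: list = []
    serial = 0
    for k, m_c in zip(keys, cgs_per_cell):
        members = np.array(cells[k])
        rng.shuffle(members)
        if m_c == 0:
            m_c = 1  # degenerate apportionment: give the cell one CG anyway
        sizes = _largest_remainder(rng.gamma(4.0, size=m_c), len(members))
        start = 0
        for sz in sizes:
            serial += 1
            cid = f"g{k[0]}{'m' if k[1] else 'f'}c{serial}"
            cg_ids.append(cid)
            for i in members[start : start + sz]:
                cg_of[int(i)] = cid
            start += sz

    cg_eff = {c: rng.normal(0.0, np.sqrt(cfg.sigma2_cg)) for c in cg_ids}

    dams = sorted({int(pedigree.dam_idx[i]) for i in pheno if pedigree.dam_idx[i] >= 0})
    pe_eff_idx = {di: rng.normal(0.0, np.sqrt(cfg.sigma2_pe)) for di in dams}

    mean_age, sd_age = cfg.age_mean_sd
    if sd_age > 0:
        lo = (cfg.min_age - mean_age) / sd_age
        ages = stats.truncnorm.rvs(lo, np.inf, loc=mean_age, scale=sd_age, size=n_ph, random_state=rng)
    else:
        ages = np.full(n_ph, mean_age)
    eps = rng.normal(0.0, np.sqrt(cfg.sigma2_e), size=n_ph)

    b1, b2 = cfg.beta_age
    records: list[PhenotypeRecord] = []
    for k, i in enumerate(pheno):
        i = int(i)
        xc = ages[k] - mean_age
        val = cfg.mu + b1 * xc + b2 * xc * xc + u[i, 0]
        val += (1.0 + u[i, 1]) * cg_eff[cg_of[i]]
        di = int(pedigree.dam_idx[i])
        if di >= 0:
            val += pe_eff_idx[di]
        val += eps[k]
        records.append(
            PhenotypeRecord(
                animal=pedigree.ids[i],
                sire=pedigree.ids[pedigree.sire_idx[i]] if pedigree.sire_idx[i] >= 0 else None,
                dam=pedigree.ids[di] if di >= 0 else None,
                cg=cg_of[i],
                cow_age=float(ages[k]),
                value=float(val),
            )
        )
    truth = TruthBundle(
        true_intercepts={a: float(u[i, 0]) for i, a in enumerate(pedigree.ids)},
        true_slopes={a: float(u[i, 1]) for i, a in enumerate(pedigree.ids)},
        true_cg_effects={c: float(v) for c, v in cg_eff.items()},
        true_pe_effects={pedigree.ids[di]: float(v) for di, v in pe_eff_idx.items()},
    )
    return records, truth


def simulate(config: SimulationConfig):
    """Convenience wrapper: (pedigree, records, truth)."""
    ped = simulate_pedigree(config)
    records, truth = simulate_phenotypes(ped, config)
    return ped, records, truth


def write_simulation(out_dir, ped: Pedigree, records, truth: TruthBundle) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pedigree(ped, out_dir / "pedigree.tsv")
    write_phenotypes(records, out_dir / "phenotypes.tsv")
    truth.write_csv(out_dir)
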
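"""Synthetic colony generator: the testbed for every analysis stage.

Emulates a captive, matrilineal, pedigreed primate colony: harem-style
breeding with few concurrent sires (large paternal half-sibships), most
males removed from the colony as they near adulthood, overlapping
generations over three decades of births, an annual-then-thrice-yearly
measurement calendar, sexually dimorphic logistic growth with a planted
heavy/light dichotomy (heavy = larger asymptote, later midpoint, slower
rate), a calorie-composition diet-intervention era, and a trait architecture
of additive polygenes + optional single QTL + maternal household +
individual environment.  Every output is a pure function of (config, seed):
a master seed feeds named sub-streams (pedigree, genetics, phenotypes,
schedule) so stages can be re-simulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .growth import GrowthParams, logistic_size
from .pedigree import Pedigree, kinship_matrix

__all__ = [
    "SimConfig",
    "DescentRecords",
    "simulate_pedigree",
    "adult_phenotyped_ids",
    "gene_drop",
    "alleles_at",
    "ibd_matrix_at",
    "genotypes_from_descent",
    "simulate_trait",
    "simulate_growth_measurements",
    "simulate_colony",
]


def _gp(theta1, midpoint, rate) -> GrowthParams:
    return GrowthParams(theta1, -midpoint * rate, rate)


#: Body-weight growth means per (sex, cluster): dimorphism plus bimaturism
#: (heavy clusters reach larger asymptotes via later midpoints and slower
#: rates), anchored to typical adult colony weights.
DEFAULT_GROWTH_PARAMS = {
    ("F", "light"): _gp(4.9, 1.2, 1.8),
    ("F", "heavy"): _gp(5.9, 1.6, 1.5),
    ("M", "light"): _gp(6.8, 1.8, 1.5),
    ("M", "heavy"): _gp(8.1, 2.3, 1.2),
}

#: Crown-rump-length growth means per sex (cm); skeletal, faster maturing.
DEFAULT_CRL_PARAMS = {"F": _gp(44.1, 0.8, 2.5), "M": _gp(50.3, 1.0, 2.2)}


@dataclass
class SimConfig:
    """Study conditions for the synthetic colony.

    Defaults describe the colony the analyses are designed for; the trait
    architecture fields (h2, c2, h2q) are the *planted* variance shares with
    h2 the residual polygenic share (so h2 + c2 + h2q <= 1).
    """

    seed: int = 0
    # demography
    n_founder_females: int = 20
    n_founder_males: int = 8
    start_year: int = 1975
    last_birth_year: int = 2009
    female_breeding_ages: tuple = (4, 20)
    male_breeding_ages: tuple = (5, 15)
    birth_rate: float = 0.45
    n_sires_per_year: int = 10
    male_removal_rate: float = 0.6
    male_removal_age: float = 4.0
    carrying_capacity: int = 150
    n_phenotyped_target: int = 600
    # genome
    chrom_lengths: tuple = tuple([100.0] * 10)
    n_markers_per_chrom: int = 120
    allele_freq_beta: tuple = (2.0, 2.0)
    # trait architecture (variance shares of a unit-variance trait)
    h2: float = 0.65
    c2: float = 0.0
    h2q: float = 0.0
    qtl_chrom: int = 0
    qtl_cm: float = 50.0
    qtl_freq: float = 0.5
    beta_sex: float = 0.25
    # growth / measurement process
    heavy_fraction: float = 0.45
    cluster_h2: float = 0.5  # heritability of the heavy/light liability
    growth_params_by_group: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH_PARAMS))
    crl_params_by_sex: dict = field(default_factory=lambda: dict(DEFAULT_CRL_PARAMS))
    re_sd: tuple = (0.25, 0.22, 0.10)  # subject SD on (theta1, theta2, theta3)
    growth_h2: tuple = (0.6, 0.15, 0.25)  # heritable share of each parameter's SD
    resid_sd: float = 0.20  # kg, visit-level BW noise
    crl_resid_sd: float = 0.7
    crl_subject_sd: float = 1.2
    wc_slope: float = 4.3
    wc_intercept_by_sex: dict = field(default_factory=lambda: {"F": 12.0, "M": 4.0})
    wc_sd: float = 2.5
    wc_from_year: int = 2008
    measure_start_year: int = 2000
    measure_end_year: int = 2015
    thrice_yearly_from: int = 2008
    miss_rate: float = 0.07
    pregnancy_rate: float = 0.18
    pregnancy_bw_gain: float = 0.4
    pregnancy_wc_gain: float = 1.5
    # diet intervention era (majority-ID window)
    id_start: date = date(2004, 5, 1)
    id_end: date = date(2008, 2, 1)

    def validate(self) -> None:
        if self.n_founder_females < 1 or self.n_founder_males < 1:
            raise ValueError("need at least one founder of each sex")
        if not (0 <= self.h2 + self.c2 + self.h2q <= 1):
            raise ValueError("h2 + c2 + h2q must lie in [0, 1]")
        for frac in (self.h2, self.c2, self.h2q, self.heavy_fraction,
                     self.male_removal_rate, self.pregnancy_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    def streams(self):
        """Named, independent random sub-streams derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(4)
        names = ("pedigree", "genetics", "phenotypes", "schedule")
        return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimConfig, rng=None) -> Pedigree:
    """Generate a matrilineal colony pedigree with overlapping generations."""
    config.validate()
    rng = rng or config.streams()["pedigree"]
    rows = []
    # state per individual: sex, birth_year, death_year, removed_year (males)
    state: dict[str, dict] = {}

    def add(iid, sire, dam, sex, year, loc):
        death = year + rng.uniform(20.0, 26.0)
        removed = None
        if sex == "M" and sire is not None:  # colony-born males face removal
            if rng.random() < config.male_removal_rate:
                removed = year + config.male_removal_age + rng.uniform(0.0, 1.0)
        rows.append({"id": iid, "sire": sire or "0", "dam": dam or "0", "sex": sex,
                     "birth_date": date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365))),
                     "birth_location": loc})
        state[iid] = {"sex": sex, "by": year, "death": death, "removed": removed}

    fyear = config.start_year - 6
    for i in range(config.n_founder_females):
        add(f"F{i:04d}", None, None, "F", fyear - int(rng.integers(0, 6)), "SiteA")
    for i in range(config.n_founder_males):
        add(f"M{i:04d}", None, None, "M", fyear - int(rng.integers(0, 6)), "SiteA")
    next_id = 0
    n_immigrant = 0
    for year in range(config.start_year, config.last_birth_year + 1):
        alive = [i for i, s in state.items()
                 if s["by"] < year and s["death"] > year
                 and (s["removed"] is None or s["removed"] > year)]
        pop = len(alive)
        females = [i for i in alive if state[i]["sex"] == "F"
                   and config.female_breeding_ages[0] <= year - state[i]["by"] <= config.female_breeding_ages[1]]
        males = [i for i in alive if state[i]["sex"] == "M"
                 and config.male_breeding_ages[0] <= year - state[i]["by"] <= config.male_breeding_ages[1]]
        if not males:  # immigrant male joins the colony
            mid = f"MI{n_immigrant:03d}"
            n_immigrant += 1
            add(mid, None, None, "M", year - 6, "SiteA" if year < 2008 else "SiteB")
            males = [mid]
        sires = list(rng.choice(males, size=min(config.n_sires_per_year, len(males)),
                                replace=False))
        rate = config.birth_rate * min(1.0, config.carrying_capacity / max(pop, 1))
        loc = "SiteA" if year < 2008 else "SiteB"
        for dam in sorted(females):
            if rng.random() < rate:
                sire = sires[int(rng.integers(0, len(sires)))]
                sex = "F" if rng.random() < 0.5 else "M"
                add(f"V{next_id:05d}", sire, dam, sex, year, loc)
                next_id += 1
    ped = Pedigree.from_records(rows)
    ped.sim_state = state  # colony residency bookkeeping used by the simulator
    return ped


def adult_phenotyped_ids(ped: Pedigree, config: SimConfig) -> list[str]:
    """Ids with known parentage and attainable adult (age>=5) measures.

    An individual qualifies if it reaches age 5 while still resident in the
    colony during the measurement era; removed males therefore rarely
    qualify, producing the female-biased adult sample typical of colonies
    that cull maturing males.
    """
    out = []
    state = getattr(ped, "sim_state", {})
    for ind in ped.individuals:
        if ind.sire_id is None or ind.dam_id is None:
            continue
        st = state.get(ind.id)
        by = ind.birth_date.year
        leave_year = min(st["death"], st["removed"] or np.inf) if st else np.inf
        adult_from = max(by + 5.0, float(config.measure_start_year))
        if adult_from <= config.measure_end_year and adult_from < leave_year:
            out.append(ind.id)
    return out


# ---------------------------------------------------------------------------
# gene dropping


@dataclass
class DescentRecords:
    """Founder-allele descent along the genome for every individual.

    ``records[iid][c]`` is a pair of haplotypes for chromosome index ``c``;
    each haplotype is ``(ends, labels)`` where ``ends`` are ascending segment
    end positions (cM, last = chromosome length) and ``labels`` founder
    haplotype identifiers.
    """

    chrom_lengths: tuple
    chroms: list
    records: dict
    n_founder_haps: int


def _meiosis(hapA, hapB, L, rng):
    """Recombine two parental haplotypes (Haldane model, no interference)."""
    n_x = rng.poisson(L / 100.0)
    if n_x == 0:
        return hapA if rng.random() < 0.5 else hapB
    breaks = np.sort(rng.uniform(0.0, L, size=n_x))
    cur = 0 if rng.random() < 0.5 else 1
    haps = (hapA, hapB)
    ends_out, labels_out = [], []
    start = 0.0
    for x in list(breaks) + [L]:
        ends, labels = haps[cur]
        i0 = np.searchsorted(ends, start, side="right")
        i1 = np.searchsorted(ends, x, side="left")
        for i in range(i0, min(i1 + 1, len(ends))):
            seg_end = min(ends[i], x)
            if seg_end > start:
                if labels_out and labels_out[-1] == labels[i]:
                    ends_out[-1] = seg_end
                else:
                    ends_out.append(seg_end)
                    labels_out.append(labels[i])
                start = seg_end
        cur = 1 - cur
        start = x
        if ends_out:
            ends_out[-1] = x
    return np.asarray(ends_out, dtype=float), np.asarray(labels_out, dtype=np.int64)


def gene_drop(ped: Pedigree, config: SimConfig, rng=None, chroms=None) -> DescentRecords:
    """Drop uniquely-labelled founder haplotypes through the pedigree."""
    rng = rng or config.streams()["genetics"]
    if chroms is None:
        chroms = list(range(len(config.chrom_lengths)))
    # every missing-parent slot contributes a fresh, uniquely-labelled founder
    # haplotype (shared across chromosomes for that slot)
    hap_label: dict[tuple[str, int], int] = {}
    for ind in ped.individuals:
        for hap_i, parent in enumerate((ind.sire_id, ind.dam_id)):
            if parent is None:
                hap_label[(ind.id, hap_i)] = len(hap_label)
    records: dict = {}
    for ind in ped.individuals:
        per_chrom = []
        for ci, c in enumerate(chroms):
            L = config.chrom_lengths[c]
            haps = []
            for hap_i, parent in enumerate((ind.sire_id, ind.dam_id)):
                if parent is None:
                    lbl = hap_label[(ind.id, hap_i)]
                    haps.append((np.array([L]), np.array([lbl], dtype=np.int64)))
                else:
                    pA, pB = records[parent][ci]
                    haps.append(_meiosis(pA, pB, L, rng))
            per_chrom.append(tuple(haps))
        records[ind.id] = per_chrom
    return DescentRecords(config.chrom_lengths, list(chroms), records,
                          n_founder_haps=len(hap_label))


def alleles_at(descent: DescentRecords, chrom: int, pos: float, ids) -> np.ndarray:
    """(n, 2) founder-haplotype labels at a position (cM) for the given ids."""
    ci = descent.chroms.index(chrom)
    out = np.empty((len(ids), 2), dtype=np.int64)
    for k, iid in enumerate(ids):
        try:
            haps = descent.records[iid][ci]
        except KeyError:
            raise KeyError(f"no descent record for id {iid!r}") from None
        for h in (0, 1):
            ends, labels = haps[h]
            out[k, h] = labels[min(np.searchsorted(ends, pos, side="right"),
                                   len(labels) - 1)]
    return out


def ibd_matrix_at(descent: DescentRecords, chrom: int, pos: float, ids) -> np.ndarray:
    """Realized proportion of alleles shared IBD at a position.

    Off-diagonal entries lie in {0, 0.5, 1} for non-inbred pairs; the
    diagonal is 1 + (locus autozygosity), so E[pi] = 2*Phi on the same
    covariance scale as the polygenic kernel.
    """
    lab = alleles_at(descent, chrom, pos, ids)
    a0, a1 = lab[:, 0], lab[:, 1]
    # sum-over-allele-pairs convention: E[pi] = 2*Phi holds exactly, including
    # under inbreeding (the diagonal becomes 1 + autozygosity automatically)
    pi = 0.5 * (
        (a0[:, None] == a0[None, :]).astype(float)
        + (a0[:, None] == a1[None, :])
        + (a1[:, None] == a0[None, :])
        + (a1[:, None] == a1[None, :])
    )
    return pi


def genotypes_from_descent(descent: DescentRecords, config: SimConfig, rng=None,
                           ids=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biallelic dosage matrix + marker map from descent records.

    Founder haplotypes carry alleles drawn per marker with frequencies from
    Beta(*config.allele_freq_beta*); markers sit on a uniform cM grid.
    Returns (genotypes: ids x markers dosage 0/1/2, map: marker, chrom, cm).
    """
    rng = rng or config.streams()["genetics"]
    ids = list(ids) if ids is not None else list(descent.records)
    geno_blocks, map_rows = [], []
    a, b = config.allele_freq_beta
    for ci, c in enumerate(descent.chroms):
        L = descent.chrom_lengths[c]
        m = config.n_markers_per_chrom
        pos = np.linspace(0.0, L, m + 2)[1:-1]
        freqs = np.clip(rng.beta(a, b, size=m), 0.05, 0.95)
        founder_alleles = (rng.random((descent.n_founder_haps, m)) < freqs).astype(np.int8)
        block = np.zeros((len(ids), m), dtype=np.int8)
        for k, iid in enumerate(ids):
            for h in (0, 1):
                ends, labels = descent.records[iid][ci][h]
                idx = np.minimum(np.searchsorted(ends, pos, side="right"), len(labels) - 1)
                block[k] += founder_alleles[labels[idx], np.arange(m)]
        geno_blocks.append(block)
        for j, p in enumerate(pos):
            map_rows.append({"marker": f"c{c}m{j}", "chrom": c, "cm": float(p)})
    G = pd.DataFrame(np.hstack(geno_blocks), index=ids,
                     columns=[r["marker"] for r in map_rows])
    return G, pd.DataFrame(map_rows)


# ---------------------------------------------------------------------------
# trait architecture


def _breeding_values(ped: Pedigree, rng, diag_phi=None) -> dict[str, float]:
    """Unit-variance additive breeding values by pedigree recursion."""
    g: dict[str, float] = {}
    F = {}
    if diag_phi is not None:
        ids, phi_diag = diag_phi
        F = {i: 2.0 * d - 1.0 for i, d in zip(ids, phi_diag)}
    for ind in ped.individuals:
        s, d = ind.sire_id, ind.dam_id
        if s is None and d is None:
            g[ind.id] = rng.normal(0.0, 1.0)
        else:
            mid = 0.5 * (g.get(s, 0.0) + g.get(d, 0.0))
            seg = 0.5 - 0.25 * (F.get(s, 0.0) + F.get(d, 0.0))
            n_known = (s is not None) + (d is not None)
            if n_known == 1:  # one unknown parent contributes full variance
                seg += 0.25
            g[ind.id] = mid + rng.normal(0.0, np.sqrt(seg))
    return g


def simulate_trait(ped: Pedigree, config: SimConfig, rng=None, ids=None,
                   descent: DescentRecords | None = None, phi=None):
    """Simulate y = X beta + q + g + c + e on a unit phenotypic scale.

    Variance shares: h2q for the QTL (requires ``descent``), h2 for residual
    polygenes, c2 for the maternal household, remainder iid environment.
    Returns (y: Series indexed by ids, truth: dict of components).
    """
    config.validate()
    rng = rng or config.streams()["phenotypes"]
    if ids is None:
        ids = ped.ids
    diag = None
    if phi is not None:
        order, mat = phi
        diag = (order, np.diag(mat))
    bv = _breeding_values(ped, rng, diag)
    n = len(ids)

    def _to_share(comp, target):
        # standardise to the exact planted in-sample share; genetic drift in a
        # closed colony otherwise moves realized shares by tens of percent
        sd = comp.std()
        if target <= 0 or sd <= 0 or n < 20:
            return comp
        return comp * (np.sqrt(target) / sd)

    g = _to_share(np.array([bv[i] for i in ids]), config.h2) if config.h2 > 0 \
        else np.zeros(n)
    q = np.zeros(n)
    if config.h2q > 0:
        if descent is None:
            raise ValueError("h2q > 0 requires descent records")
        lab = alleles_at(descent, config.qtl_chrom, config.qtl_cm, ids)
        p = config.qtl_freq
        founder_allele = (rng.random(descent.n_founder_haps) < p).astype(float)
        x = founder_allele[lab[:, 0]] + founder_allele[lab[:, 1]]
        a = np.sqrt(config.h2q / (2.0 * p * (1.0 - p)))
        q = _to_share(a * (x - 2.0 * p), config.h2q)
    c = np.zeros(n)
    if config.c2 > 0:
        dams = [ped[i].dam_id for i in ids]
        effects = {}
        for k, dmm in enumerate(dams):
            key = dmm if dmm is not None else f"__solo{k}"
            if key not in effects:
                effects[key] = rng.normal(0.0, np.sqrt(config.c2))
            c[k] = effects[key]
        c = _to_share(c, config.c2)
    e_var = max(1.0 - config.h2 - config.c2 - config.h2q, 0.0)
    e = _to_share(rng.normal(size=n), e_var) if e_var > 0 else np.zeros(n)
    sex = np.array([1.0 if ped[i].sex == "M" else 0.0 for i in ids])
    y = config.beta_sex * sex + q + g + c + e
    truth = {"g": g, "q": q, "c": c, "e": e, "sex": sex, "ids": list(ids)}
    return pd.Series(y, index=list(ids), name="y"), truth


# ---------------------------------------------------------------------------
# longitudinal growth measurements


def _visit_dates(config: SimConfig):
    dates = []
    for year in range(config.measure_start_year, config.measure_end_year + 1):
        if year >= config.thrice_yearly_from:
            dates += [date(year, 3, 1), date(year, 7, 1), date(year, 11, 1)]
        else:
            dates.append(date(year, 7, 1))
    return dates


def simulate_growth_measurements(ped: Pedigree, config: SimConfig, rng=None):
    """Longitudinal BW/CRL/WC measurements with pregnancy flags.

    Each subject's BW follows its (sex, heavy/light) group logistic curve
    plus heritable and environmental parameter deviations; WC is a noisy
    linear function of BW (so heavy-cluster adults are enriched for obesity)
    and is only recorded from ``wc_from_year`` on.  Returns
    (measurements frame, subject truth frame).
    """
    config.validate()
    rng = rng or config.streams()["phenotypes"]
    state = getattr(ped, "sim_state", {})
    bv = _breeding_values(ped, rng)
    re_sd = np.asarray(config.re_sd, dtype=float)
    gh2 = np.asarray(config.growth_h2, dtype=float)
    visits = _visit_dates(config)
    rows, truth_rows = [], []
    from scipy.stats import norm

    heavy_cut = norm.ppf(1.0 - config.heavy_fraction)
    for ind in ped.individuals:
        sex = ind.sex
        # heavy/light membership is a heritable liability: obesogenic growth
        # runs in families, at marginal prevalence heavy_fraction
        liab = (np.sqrt(config.cluster_h2) * bv[ind.id]
                + np.sqrt(1.0 - config.cluster_h2) * rng.normal())
        heavy = liab > heavy_cut
        group = "heavy" if heavy else "light"
        mean = config.growth_params_by_group[(sex, group)].as_array()
        z = rng.normal(size=3)
        dev = re_sd * (np.sqrt(gh2) * bv[ind.id] + np.sqrt(1.0 - gh2) * z)
        theta = mean + dev
        theta[0] = max(theta[0], 0.5)
        theta[2] = max(theta[2], 0.2)
        crl_mean = config.crl_params_by_sex[sex].as_array().copy()
        crl_mean[0] += config.crl_subject_sd * rng.normal() + (1.5 if heavy else -1.5)
        st = state.get(ind.id)
        leave_year = min(st["death"], st["removed"] or np.inf) if st else np.inf
        truth_rows.append({"id": ind.id, "sex": sex, "group": group,
                           "theta1": theta[0], "theta2": theta[1], "theta3": theta[2]})
        for dt in visits:
            age = (dt - ind.birth_date).days / 365.25
            if age < 0.1:
                continue
            # individuals leave the colony at death/removal
            if dt.year + dt.timetuple().tm_yday / 365.25 >= leave_year:
                continue
            if rng.random() < config.miss_rate:
                continue
            pregnant = bool(sex == "F" and age >= 4.0 and rng.random() < config.pregnancy_rate)
            bw = float(logistic_size(age, theta) + rng.normal(0.0, config.resid_sd))
            if pregnant:
                bw += config.pregnancy_bw_gain
            crl = float(logistic_size(age, crl_mean) + rng.normal(0.0, config.crl_resid_sd))
            wc = np.nan
            if dt.year >= config.wc_from_year and age >= 3.0:
                wc = (config.wc_intercept_by_sex[sex] + config.wc_slope * bw
                      + rng.normal(0.0, config.wc_sd))
                if pregnant:
                    wc += config.pregnancy_wc_gain
            rows.append({"id": ind.id, "date": dt.isoformat(), "age": round(age, 4),
                         "bw": round(max(bw, 0.05), 3), "crl": round(max(crl, 5.0), 2),
                         "wc": round(wc, 2) if np.isfinite(wc) else np.nan,
                         "pregnant": pregnant})
    measurements = pd.DataFrame(rows, columns=["id", "date", "age", "bw", "crl", "wc", "pregnant"])
    truth = pd.DataFrame(truth_rows)
    return measurements, truth


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class ColonyData:
    config: SimConfig
    pedigree: Pedigree
    measurements: pd.DataFrame
    growth_truth: pd.DataFrame
    diet_timeline: list
    kinship: tuple
    descent: DescentRecords | None = None
    trait: pd.Series | None = None
    trait_truth: dict | None = None


def simulate_colony(config: SimConfig, with_descent: bool = False,
                    with_trait: bool = False) -> ColonyData:
    """Simulate pedigree, measurements and (optionally) genome + trait."""
    streams = config.streams()
    ped = simulate_pedigree(config, streams["pedigree"])
    measurements, truth = simulate_growth_measurements(ped, config, streams["phenotypes"])
    ids, phi = kinship_matrix(ped)
    descent = None
    trait = trait_truth = None
    if with_descent or (with_trait and config.h2q > 0):
        descent = gene_drop(ped, config, streams["genetics"])
    if with_trait:
        trait, trait_truth = simulate_trait(
            ped, config, streams["phenotypes"], ids=adult_phenotyped_ids(ped, config),
            descent=descent, phi=(ids, phi))
    timeline = [
        {"diet": "Standard", "start": date(1975, 1, 1).isoformat(), "end": config.id_start.isoformat()},
        {"diet": "ID", "start": config.id_start.isoformat(), "end": config.id_end.isoformat()},
        {"diet": "Standard", "start": config.id_end.isoformat(), "end": date(2016, 1, 1).isoformat()},
    ]
    return ColonyData(config, ped, measurements, truth, timeline, (ids, phi),
                      descent, trait, trait_truth)
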
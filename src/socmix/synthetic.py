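"""Synthetic cooperative-breeder populations with route-specific microbial transmission.

The generator emulates a small, closed island population of a facultative
cooperatively breeding passerine: territorial groups of 2-5 birds headed by a
dominant pair, with subordinates that may act as nest helpers. Gut-microbiome
count tables are produced with two distinct, configurable transmission routes:

* an *environmental* route — aerotolerant taxa receive a group-level
  log-abundance shift shared by every group member within a field period
  (territory-wide exposure, e.g., via shared foraging substrate), and
* a *direct-contact* route — anaerobic taxa receive persistent bird-level
  effects that are correlated within a "nest unit" (the dominant pair plus
  their helpers), the birds that physically interact at a shared nest.

Because both effect sizes are known, the downstream dyadic pipeline can be
validated by parameter recovery: with the environmental route switched on, the
aerotolerant stratum should show a within-group similarity signal; with
nest-unit sharing switched on, the anaerobic stratum should additionally show
a nest-sharing signal among within-group pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .compositional import CountTable, TaxonAnnotation

__all__ = [
    "PopulationConfig",
    "TransmissionParams",
    "BirdRecord",
    "Population",
    "SimulatedDataset",
    "build_population",
    "simulate_latent_abundances",
    "simulate_counts",
    "simulate_dataset",
    "write_simulation",
]

STATUSES = ("DomM", "DomF", "Helper", "Sub")


@dataclass
class PopulationConfig:
    """Demography and sampling design of the simulated population.

    Defaults mirror the field system the package models: ~115 territories of
    2-5 birds (expected population ~320), subordinates helping with
    sex-specific probabilities (42% of females, 20% of males), and two field
    periods (seasons) per year, the major season first.
    """

    n_groups: int = 115
    #: probability weights for group sizes 2, 3, 4, 5 (mean 2.8 birds/group)
    group_size_weights: tuple[float, ...] = (0.45, 0.35, 0.15, 0.05)
    helper_prob_female: float = 0.42
    helper_prob_male: float = 0.20
    n_periods: int = 2
    season_labels: tuple[str, str] = ("major", "minor")
    #: probability that a bird yields a usable sample in a given field period
    resample_prob: float = 0.8
    #: probability a subordinate hatched in its current territory
    natal_prob: float = 0.80
    #: probability a natal subordinate's genetic father is an extra-group male
    extra_pair_prob: float = 0.44
    start_year: int = 2017
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1 (empty population)")
        w = np.asarray(self.group_size_weights, dtype=float)
        if len(w) != 4 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("group_size_weights must be 4 nonnegative weights summing to 1")
        for name in ("helper_prob_female", "helper_prob_male", "resample_prob",
                     "natal_prob", "extra_pair_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if len(self.season_labels) != 2:
            raise ValueError("season_labels must be an ordered (major, minor) pair")


@dataclass
class TransmissionParams:
    """Microbial effect sizes and sequencing-noise settings.

    All sigmas are standard deviations on the latent log-abundance scale.
    ``sigma_env`` acts on aerotolerant taxa at the (group, period) level;
    ``rho_nest`` is the fraction of the bird-level variance of anaerobic taxa
    shared within a nest unit (dominant pair + helpers); ``sigma_bird`` is the
    persistent per-bird effect sd for anaerobic taxa; ``sigma_period`` is a
    population-wide field-period effect; ``sigma_resid`` is per-sample noise.
    """

    sigma_env: float = 0.8
    rho_nest: float = 0.4
    sigma_bird: float = 1.0
    sigma_resid: float = 0.5
    sigma_period: float = 0.5
    n_taxa_aero: int = 120
    n_taxa_anaero: int = 60
    n_taxa_unknown: int = 10
    depth_mean: float = 20000.0
    #: gamma shape of the depth distribution; depth sd = depth_mean / sqrt(shape)
    depth_dispersion: float = 25.0
    #: sd of baseline taxon log-abundances (controls abundance skew)
    sigma_taxon_base: float = 1.5

    def __post_init__(self) -> None:
        for name in ("sigma_env", "sigma_bird", "sigma_resid", "sigma_period",
                     "sigma_taxon_base"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rho_nest < 1.0:
            raise ValueError("rho_nest must be in [0, 1)")
        if self.n_taxa_aero < 1 or self.n_taxa_anaero < 1 or self.n_taxa_unknown < 0:
            raise ValueError("taxon counts must be >= 1 (unknown may be 0)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")


@dataclass
class BirdRecord:
    bird_id: str
    group_id: str
    status: str  # DomM | DomF | Helper | Sub
    sex: str     # M | F
    age_years: float
    natal_nest_id: str | None
    present_at_nest_ids: frozenset[str]
    mother_id: str | None = None
    father_id: str | None = None


@dataclass
class Population:
    birds: list[BirdRecord]
    relatedness: pd.DataFrame        # square, bird_id x bird_id
    schedule: pd.DataFrame           # one row per capture event (sample)
    nest_unit_of: dict[str, str]     # bird_id -> nest-unit id

    @property
    def bird_ids(self) -> list[str]:
        return [b.bird_id for b in self.birds]


def _draw_background_relatedness(rng: np.random.Generator) -> float:
    # Closed island population: founder pairs carry residual background
    # relatedness (unrecorded shared ancestry); mean ~0.066.
    u = rng.random()
    if u < 0.62:
        return 0.0
    if u < 0.82:
        return 0.125
    return 0.25


def build_population(config: PopulationConfig,
                     rng: np.random.Generator | None = None) -> Population:
    """Build birds, a pedigree-based relatedness matrix, and a capture schedule.

    Every group has exactly one dominant male and one dominant female;
    additional members are subordinates, labelled Helper with a sex-specific
    probability. Relatedness comes from a two-generation pedigree: natal
    subordinates are offspring of the dominant female and (barring extra-group
    paternity) the dominant male; immigrants are founders carrying only
    background relatedness.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    sizes = rng.choice([2, 3, 4, 5], size=config.n_groups,
                       p=np.asarray(config.group_size_weights, dtype=float))

    birds: list[BirdRecord] = []
    group_ids = [f"G{g:03d}" for g in range(config.n_groups)]
    dom_m: dict[str, str] = {}
    dom_f: dict[str, str] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"B{counter:04d}"

    # dominant pairs first (they may be drawn as extra-pair fathers)
    for gid in group_ids:
        bm = new_id()
        bf = new_id()
        dom_m[gid] = bm
        dom_f[gid] = bf
        for bid, status, sex in ((bm, "DomM", "M"), (bf, "DomF", "F")):
            birds.append(BirdRecord(
                bird_id=bid, group_id=gid, status=status, sex=sex,
                age_years=float(rng.uniform(2.0, 13.0)),
                natal_nest_id=f"NX_{bid}",
                present_at_nest_ids=frozenset(),  # filled after broods known
            ))

    # subordinates
    group_broods: dict[str, set[str]] = {gid: set() for gid in group_ids}
    sub_records: list[tuple[BirdRecord, str | None]] = []  # (record, brood nest)
    for gid, size in zip(group_ids, sizes):
        for _ in range(int(size) - 2):
            bid = new_id()
            sex = "M" if rng.random() < 0.5 else "F"
            p_help = config.helper_prob_male if sex == "M" else config.helper_prob_female
            status = "Helper" if rng.random() < p_help else "Sub"
            natal = rng.random() < config.natal_prob
            mother = father = None
            if natal:
                brood = f"N{gid}_{int(rng.integers(0, 2))}"
                group_broods[gid].add(brood)
                natal_nest = brood
                mother = dom_f[gid]
                if rng.random() < config.extra_pair_prob and config.n_groups > 1:
                    other = gid
                    while other == gid:
                        other = group_ids[int(rng.integers(0, config.n_groups))]
                    father = dom_m[other]
                else:
                    father = dom_m[gid]
            else:
                natal_nest = f"NX_{bid}"
            rec = BirdRecord(
                bird_id=bid, group_id=gid, status=status, sex=sex,
                age_years=float(rng.uniform(0.7, 4.0)),
                natal_nest_id=natal_nest,
                present_at_nest_ids=frozenset({natal_nest}),
                mother_id=mother, father_id=father,
            )
            birds.append(rec)
            sub_records.append((rec, natal_nest if natal else None))

    # nest attendance: parents attend all broods of their group; helpers attend
    # each brood of their group with probability 1/2 (they may have helped it)
    by_id = {b.bird_id: b for b in birds}
    for gid in group_ids:
        broods = group_broods[gid]
        for did in (dom_m[gid], dom_f[gid]):
            rec = by_id[did]
            rec.present_at_nest_ids = frozenset(set(rec.present_at_nest_ids)
                                                | {rec.natal_nest_id} | broods)
    for b in birds:
        if b.status == "Helper":
            attended = {n for n in group_broods[b.group_id] if rng.random() < 0.5}
            b.present_at_nest_ids = frozenset(set(b.present_at_nest_ids) | attended)
        elif not b.present_at_nest_ids:
            b.present_at_nest_ids = frozenset({b.natal_nest_id})

    relatedness = _pedigree_relatedness(birds, rng)
    schedule = _capture_schedule(birds, config, rng)

    nest_unit_of: dict[str, str] = {}
    for b in birds:
        if b.status in ("DomM", "DomF", "Helper"):
            nest_unit_of[b.bird_id] = f"U_{b.group_id}"
        else:
            nest_unit_of[b.bird_id] = f"U_{b.bird_id}"

    return Population(birds=birds, relatedness=relatedness,
                      schedule=schedule, nest_unit_of=nest_unit_of)


def _pedigree_relatedness(birds: list[BirdRecord],
                          rng: np.random.Generator) -> pd.DataFrame:
    """Kinship recursion over the two-generation pedigree (r = 2*kinship)."""
    ids = [b.bird_id for b in birds]
    index = {bid: i for i, bid in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))

    founders = [b for b in birds if b.mother_id is None]
    offspring = [b for b in birds if b.mother_id is not None]

    for b in founders:
        phi[index[b.bird_id], index[b.bird_id]] = 0.5
    # background relatedness between founders of the same group only (island
    # neighbourhoods); keeps between-group relatedness centred on zero
    for i, a in enumerate(founders):
        for b in founders[i + 1:]:
            if a.group_id == b.group_id:
                r = _draw_background_relatedness(rng)
                ia, ib = index[a.bird_id], index[b.bird_id]
                phi[ia, ib] = phi[ib, ia] = r / 2.0

    # offspring never parent other birds in a two-generation pedigree, so one
    # pass in list order suffices: offspring-vs-offspring entries written too
    # early are overwritten correctly when the later offspring is processed
    for b in offspring:
        k = index[b.bird_id]
        im, ifa = index[b.mother_id], index[b.father_id]
        for j in range(n):
            if j == k:
                continue
            phi[k, j] = phi[j, k] = 0.5 * (phi[im, j] + phi[ifa, j])
        phi[k, k] = 0.5 * (1.0 + phi[im, ifa])

    r = 2.0 * phi
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, 0.0, 1.0)
    return pd.DataFrame(r, index=ids, columns=ids)


def _capture_schedule(birds: list[BirdRecord], config: PopulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """One row per capture event: each bird sampled with prob resample_prob
    per field period; covariates span day-in-season 0-97 and 0-634 minutes
    after sunrise."""
    rows = []
    s = 0
    for p in range(config.n_periods):
        year = config.start_year + p // 2
        season = config.season_labels[p % 2]
        period_id = f"{year}_{season}"
        for b in birds:
            if rng.random() >= config.resample_prob:
                continue
            s += 1
            rows.append({
                "sample_id": f"S{s:05d}",
                "bird_id": b.bird_id,
                "group_id": b.group_id,
                "period_id": period_id,
                "season": season,
                "year": year,
                "status": b.status,
                "sex": b.sex,
                "age_years": round(b.age_years + 0.5 * p, 3),
                "day_in_season": int(rng.integers(0, 98)),
                "minutes_after_sunrise": int(rng.integers(0, 635)),
                "natal_nest_id": b.natal_nest_id,
                "present_at_nest_ids": ";".join(sorted(b.present_at_nest_ids)),
            })
    if not rows:
        raise ValueError("capture schedule is empty; raise resample_prob or n_periods")
    return pd.DataFrame(rows)


def simulate_latent_abundances(population: Population, params: TransmissionParams,
                               rng: np.random.Generator | None = None,
                               seed: int | None = None
                               ) -> tuple[pd.DataFrame, TaxonAnnotation]:
    """Latent log-abundances per (sample, taxon), plus the taxon annotation.

    latent[s, j] = mu_j + period effect
                   + group env draw         (aerotolerant j; shared per group+period)
                   + persistent bird effect (anaerobic j; nest-unit correlated)
                   + residual

    The bird effect is u_b = sqrt(rho_nest) * v_unit(b) + sqrt(1 - rho_nest) * e_b
    per anaerobic taxon, where v is shared by the dominant pair and their
    helpers; non-helping subordinates form singleton units.
    """
    if not population.birds:
        raise ValueError("population is empty")
    if rng is None:
        rng = np.random.default_rng(seed)

    sched = population.schedule
    n_aero, n_anaero, n_unk = params.n_taxa_aero, params.n_taxa_anaero, params.n_taxa_unknown
    n_taxa = n_aero + n_anaero + n_unk
    taxon_ids = [f"t{j:04d}" for j in range(n_taxa)]
    classes = (["aerotolerant"] * n_aero + ["anaerobic"] * n_anaero
               + ["unknown"] * n_unk)
    annot = TaxonAnnotation(pd.DataFrame({
        "genus": [f"genus_{j:04d}" for j in range(n_taxa)],
        "aerotolerance": classes,
    }, index=pd.Index(taxon_ids, name="taxon_id")))

    aero_cols = np.arange(n_aero)
    anaero_cols = np.arange(n_aero, n_aero + n_anaero)

    mu = rng.normal(0.0, params.sigma_taxon_base, size=n_taxa)

    periods = sorted(sched["period_id"].unique())
    p_index = {p: i for i, p in enumerate(periods)}
    period_eff = rng.normal(0.0, params.sigma_period, size=(len(periods), n_taxa))

    groups = sorted({b.group_id for b in population.birds})
    g_index = {g: i for i, g in enumerate(groups)}
    env = rng.normal(0.0, params.sigma_env,
                     size=(len(groups), len(periods), n_aero))

    units = sorted(set(population.nest_unit_of.values()))
    u_index = {u: i for i, u in enumerate(units)}
    v_unit = rng.normal(0.0, 1.0, size=(len(units), n_anaero))
    bird_ids = population.bird_ids
    b_index = {b: i for i, b in enumerate(bird_ids)}
    e_bird = rng.normal(0.0, 1.0, size=(len(bird_ids), n_anaero))
    rho = params.rho_nest
    unit_rows = np.array([u_index[population.nest_unit_of[b]] for b in bird_ids])
    u_bird = params.sigma_bird * (np.sqrt(rho) * v_unit[unit_rows]
                                  + np.sqrt(1.0 - rho) * e_bird)

    n_samples = len(sched)
    latent = np.tile(mu, (n_samples, 1))
    p_rows = np.array([p_index[p] for p in sched["period_id"]])
    latent += period_eff[p_rows]
    g_rows = np.array([g_index[g] for g in sched["group_id"]])
    latent[:, aero_cols] += env[g_rows, p_rows]
    b_rows = np.array([b_index[b] for b in sched["bird_id"]])
    latent[:, anaero_cols] += u_bird[b_rows]
    latent += rng.normal(0.0, params.sigma_resid, size=(n_samples, n_taxa))

    latent_df = pd.DataFrame(latent, index=pd.Index(sched["sample_id"].to_numpy(),
                                                    name="sample_id"),
                             columns=taxon_ids)
    return latent_df, annot


def simulate_counts(latent: pd.DataFrame, params: TransmissionParams,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> CountTable:
    """Compound count noise: per-sample depth ~ gamma-Poisson (negative
    binomial) around ``depth_mean``; counts multinomial with softmax(latent)."""
    if params.depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    vals = latent.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("latent matrix must be finite")
    if rng is None:
        rng = np.random.default_rng(seed)

    k = params.depth_dispersion
    lam = rng.gamma(shape=k, scale=params.depth_mean / k, size=len(latent))
    depths = np.maximum(rng.poisson(lam), 1)

    # row-wise softmax with max-shift for stability
    z = vals - vals.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)

    counts = np.empty_like(vals, dtype=np.int64)
    for i in range(len(depths)):
        counts[i] = rng.multinomial(depths[i], p[i])
    return CountTable(pd.DataFrame(counts, index=latent.index.copy(),
                                   columns=latent.columns.copy()))


@dataclass
class SimulatedDataset:
    counts: CountTable
    metadata: pd.DataFrame
    annotation: TaxonAnnotation
    relatedness: pd.DataFrame
    config: PopulationConfig
    params: TransmissionParams
    seed: int


def simulate_dataset(config: PopulationConfig | None = None,
                     params: TransmissionParams | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """End-to-end simulation with a single seeded RNG stream."""
    config = config or PopulationConfig()
    params = params or TransmissionParams()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    pop = build_population(config, rng=rng)
    latent, annot = simulate_latent_abundances(pop, params, rng=rng)
    counts = simulate_counts(latent, params, rng=rng)
    return SimulatedDataset(counts=counts, metadata=pop.schedule, annotation=annot,
                            relatedness=pop.relatedness, config=config,
                            params=params, seed=seed)


def write_simulation(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write counts (TSV), metadata (CSV), taxonomy (TSV), relatedness (CSV)
    and a JSON sidecar recording all configuration values and the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.counts.write_tsv(outdir / "counts.tsv")
    ds.metadata.to_csv(outdir / "metadata.csv", index=False)
    ds.annotation.write_tsv(outdir / "taxonomy.tsv")
    ds.relatedness.to_csv(outdir / "relatedness.csv")
    sidecar = {
        "population_config": asdict(ds.config),
        "transmission_params": asdict(ds.params),
        "seed": ds.seed,
    }
    with open(outdir / "simulation.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=list)
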
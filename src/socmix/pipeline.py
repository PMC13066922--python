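"""End-to-end orchestration of the dyadic social-microbiome analysis.

Stages: (simulate or load inputs) -> sample exclusion + rarefaction + alpha
diversity -> rare-taxon filtering, CLR and Aitchison distances per
aerotolerance stratum -> within-period dyad construction -> multi-membership
mixed models (group membership, within-group social status, nest-sharing
lump) with Wald tables, VIF and Tukey-adjusted contrasts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compositional as comp
from . import dyads as dy
from . import mm
from .compositional import CountTable, TaxonAnnotation
from .synthetic import (PopulationConfig, TransmissionParams, simulate_dataset,
                        write_simulation)

__all__ = [
    "RunConfig",
    "ProcessedBundle",
    "process_bundle",
    "run_group_membership",
    "run_status_analysis",
    "run_all",
    "GROUP_FIXED_TERMS",
    "STATUS_FIXED_TERMS",
]

logger = logging.getLogger(__name__)

GROUP_FIXED_TERMS = ["same_group", "age_diff", "sex_diff", "season",
                     "tod_diff", "tis_diff", "relatedness", "shared_nest_at_hatch"]
STATUS_FIXED_TERMS = ["status_pair", "age_diff", "sex_diff", "season",
                      "tod_diff", "tis_diff", "relatedness", "shared_nest_at_hatch"]
LUMP_FIXED_TERMS = ["nest_sharing", "age_diff", "sex_diff", "season",
                    "tod_diff", "tis_diff", "relatedness", "shared_nest_at_hatch"]

ALL_STRATA = ("overall", "aerotolerant", "anaerobic")
ALL_ANALYSES = ("group_membership_alpha", "group_membership_composition",
                "status_alpha", "status_composition", "nest_sharing_lump")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (defaults follow the standard
    protocol: rarefaction depth 8000, taxa kept at >= 50 reads overall and
    >= 5% prevalence, CLR pseudocount 1)."""

    seed: int = 0
    simulate: dict | None = None          # {'population': {...}, 'transmission': {...}}
    inputs: dict | None = None            # paths: counts/taxonomy/metadata/relatedness
    rarefaction_depth: int = 8000
    min_total: int = 50
    min_prevalence: float = 0.05
    pseudocount: float = 1.0
    strata: tuple[str, ...] = ALL_STRATA
    analyses: tuple[str, ...] = ALL_ANALYSES
    tukey_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        self.strata = tuple(self.strata)
        self.analyses = tuple(self.analyses)
        if not self.strata or not self.analyses:
            raise ValueError("need at least one stratum and one analysis")
        bad = set(self.strata) - set(ALL_STRATA)
        if bad:
            raise ValueError(f"unknown strata: {sorted(bad)}")
        bad = set(self.analyses) - set(ALL_ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses: {sorted(bad)}")
        if self.simulate is None and self.inputs is None:
            self.simulate = {}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ProcessedBundle:
    """All per-sample and per-pair intermediates needed by the models."""
    metadata: pd.DataFrame
    alpha: pd.DataFrame
    distances: dict
    relatedness: pd.DataFrame
    dyads: pd.DataFrame
    filtered_counts: dict = field(default_factory=dict)

    def within_group(self) -> pd.DataFrame:
        return dy.filter_within_group(self.dyads)


def _load_inputs(cfg: RunConfig):
    if cfg.inputs is not None:
        counts = CountTable.read_tsv(cfg.inputs["counts"])
        annot = TaxonAnnotation.read_tsv(cfg.inputs["taxonomy"])
        metadata = pd.read_csv(cfg.inputs["metadata"])
        relatedness = pd.read_csv(cfg.inputs["relatedness"], index_col=0)
        return counts, annot, metadata, relatedness, None
    sim_cfg = cfg.simulate or {}
    pop = PopulationConfig(**{**sim_cfg.get("population", {}), "seed": cfg.seed})
    trans = TransmissionParams(**sim_cfg.get("transmission", {}))
    ds = simulate_dataset(pop, trans, seed=cfg.seed)
    return ds.counts, ds.annotation, ds.metadata, ds.relatedness, ds


def process_bundle(counts: CountTable, annot: TaxonAnnotation,
                   metadata: pd.DataFrame, relatedness: pd.DataFrame,
                   cfg: RunConfig, rng: np.random.Generator | None = None
                   ) -> ProcessedBundle:
    """Run the per-sample stages and build the dyadic dataset.

    Samples below the rarefaction depth are excluded from *all* analyses.
    Alpha diversity uses a single seeded rarefaction draw; composition uses
    the unrarefied counts of the retained samples, filtered and CLR-transformed
    per stratum (strata are re-closed: subset, re-filter, re-CLR).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rarefied = comp.rarefy(counts, cfg.rarefaction_depth, rng=rng)
    kept = rarefied.sample_ids
    n_dropped = counts.shape[0] - len(kept)
    if n_dropped:
        logger.info("excluded %d samples below %d reads", n_dropped,
                    cfg.rarefaction_depth)
    alpha = comp.alpha_diversity(rarefied)
    metadata = metadata.loc[metadata["sample_id"].isin(kept)].reset_index(drop=True)
    counts_kept = counts.select_samples(metadata["sample_id"])

    filtered = comp.filter_taxa(counts_kept, cfg.min_total, cfg.min_prevalence)
    distances = {}
    filtered_counts = {}
    for stratum in cfg.strata:
        if stratum == "overall":
            sub = filtered
        else:
            sub = comp.subset_by_aerotolerance(filtered, annot, stratum)
            sub = comp.filter_taxa(sub, cfg.min_total, cfg.min_prevalence)
        filtered_counts[stratum] = sub
        clr = comp.clr_transform(sub, cfg.pseudocount)
        distances[stratum] = comp.aitchison_distances(clr)

    dyad_table = dy.build_dyads(metadata, distances, alpha, relatedness)
    return ProcessedBundle(metadata=metadata, alpha=alpha, distances=distances,
                           relatedness=relatedness, dyads=dyad_table,
                           filtered_counts=filtered_counts)


def _drop_constant_terms(dyad_df: pd.DataFrame, terms: list[str]) -> list[str]:
    kept = []
    for t in terms:
        if dyad_df[t].nunique() > 1:
            kept.append(t)
        else:
            logger.info("dropping constant fixed term '%s'", t)
    return kept


def _fit(dyad_df: pd.DataFrame, response: str, fixed_terms: list[str],
         protect: tuple[str, ...] = ("same_group", "status_pair", "nest_sharing")):
    """Build and fit, dropping aliased nuisance covariates if the design is
    rank deficient (possible in small within-group datasets); terms in
    ``protect`` are never dropped."""
    terms = _drop_constant_terms(dyad_df, fixed_terms)
    while True:
        try:
            design = mm.build_design(dyad_df, response, terms)
            break
        except ValueError as err:
            msg = str(err)
            if "aliased" not in msg:
                raise
            droppable = [t for t in terms if t not in protect
                         and (f"{t}[" in msg or f"'{t}'" in msg or f" {t}," in msg
                              or msg.endswith(t) or f"'{t}'" in msg or t in msg)]
            candidates = droppable or [t for t in terms if t not in protect]
            if not candidates:
                raise
            logger.warning("dropping aliased/confounded fixed term '%s'",
                           candidates[-1])
            terms = [t for t in terms if t != candidates[-1]]
    fit = mm.fit_reml(design)
    table = mm.wald_table(fit)
    vifs = mm.vif(design) if len(terms) > 1 else {}
    return fit, table, design, vifs


def format_fit_table(fit: mm.MMFit) -> pd.DataFrame:
    """Publication-style table: reference levels as '—' rows, significance
    flagged '*' (p < 0.05) and '.' (p < 0.10)."""
    base = mm.wald_table(fit)
    rows = []
    emitted_factor = set()
    name_to_row = {r["term"]: r for _, r in base.iterrows()}
    for name in fit.x_names:
        for fac, (ref, rest) in fit.design.factors.items():
            first_col = f"{fac}[{rest[0]}]" if rest else None
            if name == first_col and fac not in emitted_factor:
                rows.append({"term": f"{fac}[{ref}] (reference)", "beta": "—",
                             "se": "—", "statistic": "—", "df": "—", "p": "—",
                             "sig": ""})
                emitted_factor.add(fac)
        r = name_to_row[name]
        p = float(r["p"])
        sig = "*" if p < 0.05 else ("." if p < 0.10 else "")
        rows.append({"term": name, "beta": round(float(r["beta"]), 6),
                     "se": round(float(r["se"]), 6),
                     "statistic": round(float(r["statistic"]), 4),
                     "df": round(float(r["df"]), 2), "p": round(p, 6),
                     "sig": sig})
    return pd.DataFrame(rows)


def run_group_membership(bundle: ProcessedBundle, stratum: str,
                         response: str = "composition"):
    """Between/within breeding-group similarity model.

    ``response`` is 'composition' (negated Aitchison distance of the stratum)
    or 'richness'/'shannon' (negated absolute alpha-diversity difference,
    overall rarefied table).
    """
    if response == "composition":
        col = f"neg_distance_{stratum}"
    elif response in ("richness", "shannon"):
        col = f"neg_{response}_diff"
    else:
        raise ValueError(f"unknown response '{response}'")
    fit, table, design, vifs = _fit(bundle.dyads, col, GROUP_FIXED_TERMS)
    return fit, format_fit_table(fit), vifs


def run_status_analysis(bundle: ProcessedBundle, stratum: str,
                        response: str = "composition", lump: bool = False,
                        tukey_alpha: float = 0.05):
    """Within-group social-status model (5 status-pair categories, Dom-Dom
    reference), or the 2-level nest-sharing lump when ``lump`` is set.

    Tukey-adjusted pairwise contrasts are run when the omnibus Wald test on
    the status factor is significant at ``tukey_alpha``.
    """
    within = bundle.within_group()
    if response == "composition":
        col = f"neg_distance_{stratum}"
    elif response in ("richness", "shannon"):
        col = f"neg_{response}_diff"
    else:
        raise ValueError(f"unknown response '{response}'")
    factor = "nest_sharing" if lump else "status_pair"
    if within[factor].nunique() < 2:
        raise ValueError(f"fewer than 2 observed categories of '{factor}'")
    terms = [factor] + [t for t in STATUS_FIXED_TERMS if t != "status_pair"]
    fit, table, design, vifs = _fit(within, col, terms)
    contrasts = None
    omnibus = mm.omnibus_wald(fit, factor)
    if not lump and omnibus[3] < tukey_alpha:
        contrasts = mm.tukey_contrasts(fit, factor)
    return fit, format_fit_table(fit), contrasts, omnibus, vifs


def _fit_record(fit: mm.MMFit, vifs: dict, cfg: RunConfig, extra: dict | None = None):
    rec = {
        "varcomp": fit.varcomp,
        "reml_loglik": fit.reml_loglik,
        "converged": fit.converged,
        "singular": fit.singular,
        "n_obs": fit.n_obs,
        "n_levels": fit.n_levels,
        "vif": vifs,
        "seed": cfg.seed,
        "options": {"rarefaction_depth": cfg.rarefaction_depth,
                    "min_total": cfg.min_total,
                    "min_prevalence": cfg.min_prevalence,
                    "pseudocount": cfg.pseudocount,
                    "tukey_adjustment": "single-step multivariate normal"},
    }
    if extra:
        rec.update(extra)
    return rec


def run_all(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute every requested stage and write all artefacts to ``outdir``.

    Outputs are deterministic given the seed (no timestamps), so rerunning
    with the same configuration reproduces every file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tables").mkdir(exist_ok=True)
    log_lines = [f"socmix run, seed={cfg.seed}",
                 f"config: {json.dumps(asdict(cfg), default=list, sort_keys=True)}"]

    counts, annot, metadata, relatedness, ds = _load_inputs(cfg)
    if ds is not None:
        write_simulation(ds, outdir / "simulated_input")
        log_lines.append("stage simulate: "
                         f"{counts.shape[0]} samples x {counts.shape[1]} taxa")

    rng = np.random.default_rng(cfg.seed)
    try:
        bundle = process_bundle(counts, annot, metadata, relatedness, cfg, rng=rng)
    except Exception as err:
        raise RuntimeError(f"stage 'process' failed: {err}") from err
    bundle.alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t",
                        index_label="sample_id")
    for stratum, dm in bundle.distances.items():
        pd.DataFrame(np.asarray(dm.data), index=dm.ids, columns=dm.ids).to_csv(
            outdir / f"distances_{stratum}.tsv", sep="\t", index_label="sample_id")
    bundle.dyads.to_csv(outdir / "dyads.csv", index=False)
    log_lines.append(f"stage process: {len(bundle.metadata)} samples retained, "
                     f"{len(bundle.dyads)} dyads")

    summary: list[str] = ["# socmix analysis summary", ""]
    fits_json: dict[str, dict] = {}

    def emit(name: str, fit, table: pd.DataFrame, vifs: dict,
             contrasts: pd.DataFrame | None = None, extra: dict | None = None):
        path = outdir / "tables" / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        fits_json[name] = _fit_record(fit, vifs, cfg, extra)
        summary.extend([f"## {name}", "", table.to_string(index=False), ""])
        if contrasts is not None:
            cpath = outdir / "tables" / f"{name}_contrasts.tsv"
            contrasts.to_csv(cpath, sep="\t", index=False)
            summary.extend(["### Tukey-adjusted contrasts", "",
                            contrasts.to_string(index=False), ""])

    for analysis in cfg.analyses:
        try:
            if analysis == "group_membership_alpha":
                for resp in ("richness", "shannon"):
                    fit, table, vifs = run_group_membership(bundle, "overall", resp)
                    emit(f"group_membership_alpha_{resp}", fit, table, vifs)
            elif analysis == "group_membership_composition":
                for stratum in cfg.strata:
                    fit, table, vifs = run_group_membership(bundle, stratum,
                                                            "composition")
                    emit(f"group_membership_composition_{stratum}", fit, table, vifs)
            elif analysis == "status_alpha":
                for resp in ("richness", "shannon"):
                    fit, table, contrasts, omni, vifs = run_status_analysis(
                        bundle, "overall", resp, tukey_alpha=cfg.tukey_alpha)
                    emit(f"status_alpha_{resp}", fit, table, vifs, contrasts,
                         {"omnibus_status": omni})
            elif analysis == "status_composition":
                for stratum in cfg.strata:
                    fit, table, contrasts, omni, vifs = run_status_analysis(
                        bundle, stratum, "composition", tukey_alpha=cfg.tukey_alpha)
                    emit(f"status_composition_{stratum}", fit, table, vifs,
                         contrasts, {"omnibus_status": omni})
            elif analysis == "nest_sharing_lump":
                for stratum in cfg.strata:
                    fit, table, contrasts, omni, vifs = run_status_analysis(
                        bundle, stratum, "composition", lump=True,
                        tukey_alpha=cfg.tukey_alpha)
                    emit(f"nest_sharing_lump_{stratum}", fit, table, vifs)
        except Exception as err:
            raise RuntimeError(f"stage '{analysis}' failed: {err}") from err
        log_lines.append(f"stage {analysis}: done")

    with open(outdir / "fits.json", "w") as fh:
        json.dump(fits_json, fh, indent=2, sort_keys=True, default=float)
    (outdir / "summary.md").write_text("\n".join(summary))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
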
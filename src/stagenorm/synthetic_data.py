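"""Synthetic multi-site early/advanced RNA-seq cohorts with planted truth.

The generator emulates the structure of staged tumour cohorts pulled
from a Xena-style portal: several primary sites, each with an
early-stage and an advanced-stage group, counts on the log2(x+1) scale,
co-expressed gene modules driven by shared latent factors, site- and
subtype-specific early-to-advanced fold changes, and survival times tied
to one prognostic gene.  Every planted feature is returned as ground
truth so recovery tests can score the pipeline against it.

Counts are negative-binomial (gamma-Poisson): overdispersion is the
standard behaviour of bulk RNA-seq counts.  Library-size and GC biases
and batch effects are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from stagenorm.io_formats import (
    GenomicMatrix,
    SampleMetadata,
    write_genomic_matrix,
    write_phenotypes,
    write_survival,
)

#: early/advanced group sizes of the five default cohorts (lymph node,
#: bronchus and lung, cervix uteri, liver, testis) — the sample-size
#: regime the method is meant for.
DEFAULT_COHORT_SIZES: tuple[tuple[int, int], ...] = ((4, 8), (28, 28), (8, 22), (20, 6), (15, 15))


@dataclass
class SubtypeSplit:
    """Two progression profiles within one site plus a mixing fraction.

    Advanced samples of the site are split into subtype ``a`` (fraction
    ``fraction``) and subtype ``b`` (the rest), each with its own
    per-module natural-log fold-change vector.
    """

    lfc_a: np.ndarray
    lfc_b: np.ndarray
    fraction: float = 0.5

    def __post_init__(self) -> None:
        self.lfc_a = np.asarray(self.lfc_a, dtype=float)
        self.lfc_b = np.asarray(self.lfc_b, dtype=float)
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"mixing fraction must be in (0,1), got {self.fraction}")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic multi-cohort study.

    ``progression_lfc[s, m]`` is the natural-log fold change applied to
    module ``m`` in site ``s`` when moving from the anchored stage to
    the other.  With ``anchor='early'`` (default) the baseline is the
    early-stage mean and advanced samples are shifted by the fold
    change; ``anchor='advanced'`` fixes the advanced-stage mean instead
    and shifts the early samples down — useful for scenarios where two
    sites share identical advanced-stage distributions but differ in how
    far they progressed to reach them.
    """

    n_sites: int = 5
    cohort_sizes: tuple[tuple[int, int], ...] = DEFAULT_COHORT_SIZES
    n_genes: int = 300
    n_modules: int = 3
    module_size: int = 40
    baseline_mean: float = 100.0
    dispersion: float = 20.0
    latent_sd: float = 0.6
    background_sd: float = 0.2
    progression_lfc: Optional[np.ndarray] = None
    subtype_split: dict[int, SubtypeSplit] = field(default_factory=dict)
    anchor: str = "early"
    prognostic_gene: int = 0
    hazard_coef: float = 0.0
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cohort_sizes) != self.n_sites:
            raise ValueError(
                f"cohort_sizes has {len(self.cohort_sizes)} entries for n_sites={self.n_sites}"
            )
        if any(ne <= 0 or na <= 0 for ne, na in self.cohort_sizes):
            raise ValueError("all per-site early/advanced counts must be positive")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module_size * n_modules exceeds n_genes")
        if self.anchor not in ("early", "advanced"):
            raise ValueError(f"anchor must be 'early' or 'advanced', got {self.anchor!r}")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.progression_lfc is None:
            self.progression_lfc = np.zeros((self.n_sites, self.n_modules))
        else:
            self.progression_lfc = np.asarray(self.progression_lfc, dtype=float)
            if self.progression_lfc.shape != (self.n_sites, self.n_modules):
                raise ValueError(
                    f"progression_lfc shape {self.progression_lfc.shape} != "
                    f"({self.n_sites}, {self.n_modules})"
                )

    @property
    def site_ids(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a simulated cohort."""

    module_membership: dict[str, int]
    subtype_labels: dict[str, str]
    prognostic_gene_id: str
    true_lfc: np.ndarray
    site_of_sample: dict[str, str]
    stage_of_sample: dict[str, str]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenomicMatrix, list[SampleMetadata], GroundTruth]:
    """Draw one multi-site early/advanced cohort.

    Counts for gene g in sample j are negative-binomial with mean
    ``baseline_mean * exp(z[m(g), j]) * exp(lfc)`` where z is a shared
    per-sample latent factor for the gene's module (inducing
    co-expression) and lfc is the site/subtype/stage-dependent
    progression term.  Background genes get independent log-normal
    wobble instead of a shared factor.  Deterministic given the seed.
    """
    root = np.random.SeedSequence(config.seed)
    ss_latent, ss_counts, ss_subtype = root.spawn(3)
    rng_latent = np.random.default_rng(ss_latent)
    rng_counts = np.random.default_rng(ss_counts)
    rng_subtype = np.random.default_rng(ss_subtype)

    gene_ids = config.gene_ids()
    module_of_gene = np.full(config.n_genes, -1, dtype=int)
    for m in range(config.n_modules):
        module_of_gene[m * config.module_size : (m + 1) * config.module_size] = m

    sample_ids: list[str] = []
    site_of_sample: dict[str, str] = {}
    stage_of_sample: dict[str, str] = {}
    subtype_labels: dict[str, str] = {}
    sample_site_idx: list[int] = []
    sample_is_advanced: list[bool] = []
    sample_lfc_rows: list[np.ndarray] = []

    for s, (n_early, n_advanced) in enumerate(config.cohort_sizes):
        site = config.site_ids[s]
        split = config.subtype_split.get(s)
        if split is not None:
            n_a = max(1, min(n_advanced - 1, int(round(split.fraction * n_advanced))))
            subtype_of_adv = np.array(["a"] * n_a + ["b"] * (n_advanced - n_a))
            rng_subtype.shuffle(subtype_of_adv)
        else:
            subtype_of_adv = np.array(["a"] * n_advanced)
        for k in range(n_early):
            sid = f"{site}_E{k + 1:03d}"
            sample_ids.append(sid)
            site_of_sample[sid] = site
            stage_of_sample[sid] = "early"
            sample_site_idx.append(s)
            sample_is_advanced.append(False)
            sample_lfc_rows.append(config.progression_lfc[s])
        for j in range(n_advanced):
            sid = f"{site}_A{j + 1:03d}"
            sample_ids.append(sid)
            site_of_sample[sid] = site
            stage_of_sample[sid] = "advanced"
            sample_site_idx.append(s)
            sample_is_advanced.append(True)
            if split is not None:
                sub = subtype_of_adv[j]
                subtype_labels[sid] = f"{site}_{sub}"
                sample_lfc_rows.append(split.lfc_a if sub == "a" else split.lfc_b)
            else:
                subtype_labels[sid] = site
                sample_lfc_rows.append(config.progression_lfc[s])

    n_samples = len(sample_ids)
    is_advanced = np.asarray(sample_is_advanced)
    lfc_by_sample = np.vstack(sample_lfc_rows)  # (n_samples, n_modules)

    # stage-dependent shift: anchored stage sits at the baseline
    if config.anchor == "early":
        stage_shift = np.where(is_advanced[:, None], lfc_by_sample, 0.0)
    else:
        stage_shift = np.where(is_advanced[:, None], 0.0, -lfc_by_sample)

    z = rng_latent.normal(0.0, config.latent_sd, size=(config.n_modules, n_samples))

    log_mu = np.full((config.n_genes, n_samples), np.log(config.baseline_mean))
    in_module = module_of_gene >= 0
    log_mu[in_module] += z[module_of_gene[in_module]]
    log_mu[in_module] += stage_shift[:, module_of_gene[in_module]].T
    n_bg = int((~in_module).sum())
    if n_bg:
        log_mu[~in_module] += rng_latent.normal(
            0.0, config.background_sd, size=(n_bg, n_samples)
        )

    mu = np.exp(log_mu)
    # gamma-Poisson mixture == negative binomial with size `dispersion`
    lam = rng_counts.gamma(shape=config.dispersion, scale=mu / config.dispersion)
    counts = rng_counts.poisson(lam).astype(float)

    values = pd.DataFrame(np.log2(counts + 1.0), index=gene_ids, columns=sample_ids)
    matrix = GenomicMatrix(values=values, unit="log2_plus1")

    metadata = [
        SampleMetadata(
            sample_id=sid,
            primary_site=site_of_sample[sid],
            stage=stage_of_sample[sid],
            clinical={"subtype": subtype_labels.get(sid)},
        )
        for sid in sample_ids
    ]
    truth = GroundTruth(
        module_membership={g: int(m) for g, m in zip(gene_ids, module_of_gene)},
        subtype_labels={s: subtype_labels[s] for s in sample_ids if stage_of_sample[s] == "advanced"},
        prognostic_gene_id=gene_ids[config.prognostic_gene],
        true_lfc=config.progression_lfc.copy(),
        site_of_sample=site_of_sample,
        stage_of_sample=stage_of_sample,
    )
    return matrix, metadata, truth


def simulate_survival(
    expression: Sequence[float] | np.ndarray,
    sample_ids: Sequence[str],
    hazard_coef: float,
    censor_rate: float,
    seed: int,
    baseline_hazard: float = np.log(2) / 1000.0,
) -> pd.DataFrame:
    """Draw exponential survival times tied to one gene's expression.

    The per-patient event rate is ``baseline_hazard * exp(hazard_coef *
    x)`` where x is the (normalized) expression of the prognostic gene;
    the default baseline puts the median survival of an average patient
    near 1000 days.  Censoring is an independent Uniform(0, tau) time,
    with tau calibrated so the expected censored fraction matches
    ``censor_rate``.  Deterministic given the seed.
    """
    x = np.asarray(expression, dtype=float)
    if len(x) != len(sample_ids):
        raise ValueError("expression and sample_ids length mismatch")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rate = baseline_hazard * np.exp(hazard_coef * x)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate <= 0.0:
        times, events = t_event, np.ones(len(x), dtype=int)
    else:
        tau = _calibrate_censor_tau(t_event, censor_rate)
        c = rng.uniform(0.0, tau, size=len(x))
        events = (t_event <= c).astype(int)
        times = np.minimum(t_event, c)
    return pd.DataFrame(
        {"sample_id": list(sample_ids), "os_days": times, "os_event": events}
    )


def _calibrate_censor_tau(t_event: np.ndarray, censor_rate: float) -> float:
    """Solve for tau such that mean_i P(U(0,tau) < t_i) = censor_rate."""

    def censored_fraction(tau: float) -> float:
        return float(np.mean(np.minimum(t_event / tau, 1.0)))

    lo, hi = np.min(t_event) * 1e-6 + 1e-12, np.max(t_event) * 1e6 + 1.0
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_fraction(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def module_recovery_config(seed: int = 0) -> SimulationConfig:
    """Default-regime cohort with three planted 40-gene modules."""
    return SimulationConfig(seed=seed)


def progression_contrast_config(seed: int = 0) -> SimulationConfig:
    """Two cancer types with identical advanced-stage count distributions.

    Each type progresses through its own module: type 1 shows a 4-fold
    early-to-advanced increase in module 1 (fold 1 in module 2), type 2
    the mirror image.  Anchoring the advanced stage makes the advanced
    count distributions of the two types identical, so clustering raw
    advanced counts cannot tell the types apart while the
    early-referenced log ratios separate them.  Within-type latent
    variability is set below the 4-fold progression signal
    (latent_sd 0.3 versus ln 4 = 1.39), the idealized-contrast regime.
    """
    return SimulationConfig(
        n_sites=2,
        cohort_sizes=((15, 15), (15, 15)),
        n_genes=100,
        n_modules=2,
        module_size=40,
        anchor="advanced",
        latent_sd=0.3,
        progression_lfc=np.array([[np.log(4.0), 0.0], [0.0, np.log(4.0)]]),
        seed=seed,
    )


def write_fixture_study(
    out_dir: str | Path, config: Optional[SimulationConfig] = None
) -> dict[str, Path]:
    """Write a complete toy study (matrix, phenotypes, biotypes, survival, GMT).

    Used by the CLI ``simulate`` subcommand and by tests that exercise
    the file-based pipeline end to end.
    """
    from stagenorm.io_formats import write_biotypes, write_gmt, GeneSetCollection
    from stagenorm.preprocess import to_raw_counts
    from stagenorm.stage_normalize import build_staged_set, tissue_correct

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimulationConfig()
    matrix, metadata, truth = simulate_cohort(config)

    paths = {
        "matrix": out_dir / "expression_log2.tsv",
        "phenotypes": out_dir / "phenotypes.tsv",
        "biotypes": out_dir / "biotypes.tsv",
        "survival": out_dir / "survival.tsv",
        "gene_sets": out_dir / "gene_sets.gmt",
        "truth": out_dir / "ground_truth.tsv",
    }
    write_genomic_matrix(matrix, paths["matrix"])
    write_phenotypes(metadata, paths["phenotypes"])
    write_biotypes({g: "protein_coding" for g in matrix.gene_ids}, paths["biotypes"])

    counts = to_raw_counts(matrix)
    staged = build_staged_set(counts, metadata)
    corrected = tissue_correct(staged)
    prog = corrected.L.loc[truth.prognostic_gene_id]
    surv = simulate_survival(
        prog.to_numpy(), list(prog.index), config.hazard_coef, config.censor_rate, config.seed
    )
    write_survival(surv, paths["survival"])

    # one gene set per planted module plus a decoy, so enrichment runs end to end
    sets: dict[str, tuple[str, list[str]]] = {}
    for m in range(config.n_modules):
        members = [g for g, mm in truth.module_membership.items() if mm == m]
        sets[f"planted_module_{m + 1}"] = (f"genes of planted module {m + 1}", members)
    rng = np.random.default_rng(config.seed + 1)
    decoy = list(rng.choice(matrix.gene_ids, size=min(25, len(matrix.gene_ids)), replace=False))
    sets["decoy_set"] = ("random decoy gene set", decoy)
    write_gmt(GeneSetCollection(sets=sets), paths["gene_sets"])

    pd.DataFrame(
        {
            "gene_id": list(truth.module_membership),
            "module": list(truth.module_membership.values()),
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
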
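"""Synthetic single-embryo RNA-seq study generator with planted truth.

Emulates the design of the cycle-12-arrest experiment: control embryos
sampled at C12, C13, early C14 and late C14, and cycle-12-arrested
embryos sampled 15, 30, 50 and 70 minutes after mitosis 11, with 2-3
replicate embryos per condition. Expected per-gene transcript abundance
combines an exponentially decaying maternal pool with zygotic accrual
limited to the productive windows of the cell-cycle schedule (arrested
embryos accrue continuously through their open-ended interphase). Counts
are negative-binomial with log-normal library sizes.

Every gene carries planted ground-truth labels (arrest-response group,
maternal clearance, N/C-like vs time-like delay class) for recovery
tests. Default parameter ranges were chosen so that the noiseless
expected profiles satisfy the corresponding classification rules with a
comfortable margin (>= ~0.5 Log2 units at each compared pair); recovery
rates under noise therefore measure robustness, not luck.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from zgakit.expression import ExpressionMatrix
from zgakit.schedule import CycleSchedule, default_schedule
from zgakit.window_model import eclipse_time, productive_window

GENE_CLASSES = ("maternal_only", "zygotic_only", "maternal_and_zygotic", "silent")

#: catalog composition: a large stable maternal background keeps library
#: composition roughly constant so CPM comparisons track true abundance
DEFAULT_CLASS_MIX = {
    "zygotic_only": 0.28,
    "maternal_and_zygotic": 0.06,
    "maternal_only": 0.41,
    "silent": 0.25,
}
DEFAULT_LENGTH_DISTRIBUTION = {"log_mean": np.log(3.0), "log_sigma": 1.0, "max_kb": 50.0}


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    gene_class: str
    tu_length_kb: float = 0.0
    maternal_initial: float = 0.0  # expected transcripts at mitosis 11
    decay_rate: float = 0.0  # per minute
    decay_onset_min: float = 0.0
    zygotic_rate: float = 0.0  # completed transcripts/min/nucleus potential
    planted_group: str = "none"  # {1, 2, 3, none}
    planted_delay_class: str = "none"  # {nc_like, time_like, none}

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.gene_class == "zygotic_only" and self.maternal_initial != 0:
            raise ValueError("zygotic_only genes must have maternal_initial = 0")
        if self.gene_class == "maternal_only" and self.zygotic_rate != 0:
            raise ValueError("maternal_only genes must have zygotic_rate = 0")
        if self.tu_length_kb < 0 or self.decay_rate < 0:
            raise ValueError("lengths and decay rates must be >= 0")


@dataclass(frozen=True)
class DesignPoint:
    """One experimental condition: where an embryo is in the schedule when
    it is collected."""

    condition: str  # control | arrested
    cycle_label: str  # C12, C13, C14E, C14L or arrest minutes
    minutes: float  # minutes after mitosis 11
    cycle: int  # cell cycle the embryo is in at collection
    nuclei_factor: float  # nucleus count relative to cycle 12


@dataclass(frozen=True)
class EmbryoDesign:
    replicates: int = 3
    nuclei_base: float = 1.0  # cycle-12 nucleus count, relative units
    library_median: float = 5e5
    library_log_sigma: float = 0.15
    nb_dispersion: float = 0.1
    arrest_minutes: tuple[float, ...] = (15.0, 30.0, 50.0, 70.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicate embryos per condition")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


def design_points(
    design: EmbryoDesign, schedule: CycleSchedule
) -> list[DesignPoint]:
    """Control points at mid-interphase C12/C13 and at +10'/+70' into C14,
    plus arrested points at the design's arrest times. Control nucleus
    counts double each cycle; arrested counts stay at the cycle-12 value.
    Time zero is the completion of mitosis 11."""
    i12 = schedule.interphase_min(12)
    m12 = schedule.mitosis_min(12)
    i13 = schedule.interphase_min(13)
    m13 = schedule.mitosis_min(13)
    c13_start = i12 + m12
    c14_start = c13_start + i13 + m13
    points = [
        DesignPoint("control", "C12", i12 / 2, 12, 1.0),
        DesignPoint("control", "C13", c13_start + i13 / 2, 13, 2.0),
        DesignPoint("control", "C14E", c14_start + 10.0, 14, 4.0),
        DesignPoint("control", "C14L", c14_start + 70.0, 14, 4.0),
    ]
    for t in design.arrest_minutes:
        points.append(DesignPoint("arrested", f"{t:g}", float(t), 12, 1.0))
    return points


def generate_catalog(
    n_genes: int,
    class_mix: dict[str, float] | None = None,
    length_distribution: dict[str, float] | None = None,
    seed: int = 0,
    group3_fraction: float = 0.06,
    delay_fraction: float = 0.2,
) -> list[GeneSpec]:
    """Draw a reproducible gene catalog.

    Classes are multinomial with the given mix. Planted labels: every
    zygotic_only gene is arrest-response group 1 (a fifth of them also
    carry a delay class, split evenly nc_like/time_like); every
    maternal_and_zygotic gene is group 2; decaying maternal_only genes are
    the maternal-clearance cohort, a ``group3_fraction`` of which is
    planted as group 3 (zygotic genes whose arrest profile is pure decay).
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class mix proportions must sum to 1")
    unknown = set(mix) - set(GENE_CLASSES)
    if unknown:
        raise ValueError(f"unknown gene classes in mix: {sorted(unknown)}")
    ldist = dict(DEFAULT_LENGTH_DISTRIBUTION)
    if length_distribution:
        ldist.update(length_distribution)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    classes = list(mix)
    draws = rng.choice(len(classes), size=n_genes, p=[mix[c] for c in classes])
    width = len(str(max(n_genes - 1, 1)))

    catalog: list[GeneSpec] = []
    for i, ci in enumerate(draws):
        cls = classes[ci]
        gid = f"g{i:0{width}d}"
        if cls == "silent":
            spec = GeneSpec(gid, cls)
        elif cls == "zygotic_only":
            length = min(
                float(rng.lognormal(ldist["log_mean"], ldist["log_sigma"])),
                ldist["max_kb"],
            )
            delay = "none"
            if rng.random() < delay_fraction:
                delay = "nc_like" if rng.random() < 0.5 else "time_like"
            spec = GeneSpec(
                gid,
                cls,
                tu_length_kb=length,
                zygotic_rate=float(rng.uniform(1.0, 4.0)),
                planted_group="1",
                planted_delay_class=delay,
            )
        elif cls == "maternal_and_zygotic":
            spec = GeneSpec(
                gid,
                cls,
                tu_length_kb=float(rng.uniform(0.3, 1.0)),
                maternal_initial=float(rng.uniform(350.0, 650.0)),
                decay_rate=float(rng.uniform(0.08, 0.10)),
                zygotic_rate=float(rng.uniform(1.8, 2.6)),
                planted_group="2",
            )
        else:  # maternal_only: 40% stable housekeeping, 60% decaying
            if rng.random() < 0.4:
                spec = GeneSpec(
                    gid, cls, maternal_initial=float(rng.uniform(800.0, 2500.0))
                )
            else:
                spec = GeneSpec(
                    gid,
                    cls,
                    maternal_initial=float(rng.uniform(150.0, 600.0)),
                    decay_rate=float(rng.uniform(0.03, 0.07)),
                    planted_group=(
                        "3" if rng.random() < group3_fraction else "none"
                    ),
                )
        catalog.append(spec)
    if not catalog:
        raise ValueError("catalog is empty")
    return catalog


def _zygotic_accrued(
    gene: GeneSpec, point: DesignPoint, schedule: CycleSchedule, nuclei_base: float
) -> float:
    """Completed zygotic transcripts accumulated by the collection time.

    Control embryos: per elapsed cycle since mitosis 11, completed
    transcripts are rate x nuclei x productive window; within the cycle in
    progress, completions by elapsed time tau are
    rate x nuclei x max(0, min(tau, interphase) - lag - eclipse).
    Arrested embryos idle in an open-ended cycle-12 interphase, accruing
    rate x nuclei x max(0, t - lag - eclipse).
    """
    if gene.zygotic_rate == 0:
        return 0.0
    ecl = eclipse_time(gene.tu_length_kb, schedule)
    lag = schedule.lag_min
    if point.condition == "arrested":
        return (
            gene.zygotic_rate
            * nuclei_base
            * max(0.0, point.minutes - lag - ecl)
        )
    total = 0.0
    t0 = 0.0
    nuclei = nuclei_base
    for c in range(12, point.cycle + 1):
        inter = schedule.interphase_min(c)
        if c < point.cycle:
            total += gene.zygotic_rate * nuclei * productive_window(
                c, gene.tu_length_kb, schedule
            )
            t0 += inter + schedule.mitosis_min(c)
            nuclei *= 2.0
        else:
            tau = point.minutes - t0
            if not schedule.is_terminal(c):
                tau = min(tau, inter)
            total += gene.zygotic_rate * nuclei * max(0.0, tau - lag - ecl)
    return total


def expected_abundance(
    gene: GeneSpec,
    point: DesignPoint,
    schedule: CycleSchedule,
    nuclei_base: float = 1.0,
) -> float:
    """Expected transcript count for one gene at one design point:
    decaying maternal pool plus accumulated zygotic production."""
    maternal = gene.maternal_initial * np.exp(
        -gene.decay_rate * max(0.0, point.minutes - gene.decay_onset_min)
    )
    return float(maternal + _zygotic_accrued(gene, point, schedule, nuclei_base))


def expected_matrix(
    catalog: list[GeneSpec],
    design: EmbryoDesign,
    schedule: CycleSchedule,
) -> pd.DataFrame:
    """Genes x design-point expected transcript counts (no noise).
    Columns are '<condition>:<cycle_label>' keys."""
    points = design_points(design, schedule)
    data = {
        f"{p.condition}:{p.cycle_label}": [
            expected_abundance(g, p, schedule, design.nuclei_base) for g in catalog
        ]
        for p in points
    }
    return pd.DataFrame(data, index=[g.gene_id for g in catalog])


def sample_counts(
    expected: pd.DataFrame,
    design: EmbryoDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw replicate embryos for every design point.

    Per sample a library size is drawn log-normally; per gene, counts are
    negative-binomial (gamma-Poisson) with mean expectation x library
    factor and the design's dispersion (variance mu + alpha mu^2);
    dispersion 0 degenerates to Poisson. Returns the counts-stage matrix
    plus its sample-metadata table.
    """
    vals = expected.to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise ValueError("expected abundances must be finite and >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(design.seed), 23]))
    alpha = design.nb_dispersion
    columns, meta_rows = {}, []
    for key in expected.columns:
        condition, label = key.split(":", 1)
        mu_cond = expected[key].to_numpy(dtype=float)
        total = mu_cond.sum()
        for rep in range(1, design.replicates + 1):
            lib = design.library_median * rng.lognormal(0.0, design.library_log_sigma)
            mu = mu_cond * (lib / total) if total > 0 else mu_cond
            if alpha > 0:
                shape = 1.0 / alpha
                lam = rng.gamma(shape, scale=np.where(mu > 0, mu * alpha, 1.0))
                lam = np.where(mu > 0, lam, 0.0)
                counts = rng.poisson(lam)
            else:
                counts = rng.poisson(mu)
            sid = f"{condition[:4]}_{label}_r{rep}"
            columns[sid] = counts
            meta_rows.append(
                {
                    "sample_id": sid,
                    "condition": condition,
                    "cycle_label": label,
                    "minutes": _label_minutes(condition, label),
                    "replicate": rep,
                }
            )
    counts_df = pd.DataFrame(columns, index=expected.index)
    counts_df.index.name = "gene_id"
    meta = pd.DataFrame(meta_rows)
    return ExpressionMatrix(values=counts_df, stage="counts", meta=meta), meta


def _label_minutes(condition: str, label: str) -> float:
    if condition == "arrested":
        return float(label)
    return {"C12": 6.25, "C13": 25.0, "C14E": 47.5, "C14L": 107.5}.get(label, np.nan)


def delay_profiles(
    catalog: list[GeneSpec],
    schedule: CycleSchedule,
    seed: int = 0,
    cycles: tuple[int, ...] = (10, 11, 12, 13, 14),
    noise_sigma_rel: float = 0.1,
) -> pd.DataFrame:
    """Paired diploid/haploid expression-by-cycle profiles for the genes
    carrying a planted delay class.

    The diploid profile is per-nucleus productive output per cycle
    (rate x productive window; the terminal cycle uses its nominal
    interphase). nc_like genes get the diploid profile shifted one cycle
    later (haploids slow their cycles one cycle late); time_like genes get
    the unshifted profile. Gaussian noise with sigma = 10% of the profile
    amplitude is added to both.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))
    rows = {}
    for gene in catalog:
        if gene.planted_delay_class == "none":
            continue
        dip = np.array(
            [
                gene.zygotic_rate
                * max(
                    0.0,
                    schedule.interphase_min(c)
                    - schedule.lag_min
                    - eclipse_time(gene.tu_length_kb, schedule),
                )
                for c in cycles
            ]
        )
        if gene.planted_delay_class == "nc_like":
            hap = np.concatenate([[dip[0]], dip[:-1]])
        else:
            hap = dip.copy()
        amp = dip.max() - dip.min()
        sigma = noise_sigma_rel * amp
        dip = dip + rng.normal(0.0, sigma, size=dip.shape)
        hap = hap + rng.normal(0.0, sigma, size=hap.shape)
        rows[gene.gene_id] = np.concatenate([dip, hap])
    cols = [f"diploid_c{c}" for c in cycles] + [f"haploid_c{c}" for c in cycles]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.index.name = "gene_id"
    return table


@dataclass(frozen=True)
class StudyBundle:
    counts: ExpressionMatrix
    meta: pd.DataFrame
    truth: pd.DataFrame
    profiles: pd.DataFrame
    schedule: CycleSchedule
    catalog: list[GeneSpec] = field(repr=False, default_factory=list)


def truth_table(catalog: list[GeneSpec]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g.gene_id,
            "gene_class": g.gene_class,
            "tu_length_kb": g.tu_length_kb,
            "maternal_initial": g.maternal_initial,
            "decay_rate": g.decay_rate,
            "zygotic_rate": g.zygotic_rate,
            "planted_group": g.planted_group,
            "planted_maternal": g.gene_class == "maternal_only" and g.decay_rate > 0,
            "planted_delay_class": g.planted_delay_class,
        }
        for g in catalog
    ]
    return pd.DataFrame(rows).set_index("gene_id")


def make_study(
    design: EmbryoDesign | None = None,
    catalog: list[GeneSpec] | None = None,
    schedule: CycleSchedule | None = None,
    out_dir: str | Path | None = None,
    n_genes: int = 2000,
) -> StudyBundle:
    """Generate a complete synthetic study: counts, metadata, planted
    truth and delay profiles — everything the analysis pipeline needs.

    With ``out_dir`` set, writes counts.tsv, meta.tsv, truth.tsv,
    profiles.tsv and schedule.tsv there.
    """
    design = design or EmbryoDesign()
    schedule = schedule or default_schedule()
    if catalog is None:
        catalog = generate_catalog(n_genes, seed=design.seed)
    if not catalog:
        raise ValueError("catalog is empty")
    expected = expected_matrix(catalog, design, schedule)
    counts, meta = sample_counts(expected, design)
    truth = truth_table(catalog)
    profiles = delay_profiles(catalog, schedule, seed=design.seed)
    bundle = StudyBundle(counts, meta, truth, profiles, schedule, catalog)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cdf = counts.values.copy()
        cdf.index.name = "gene_id"
        cdf.to_csv(out / "counts.tsv", sep="\t")
        meta.to_csv(out / "meta.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t")
        profiles.to_csv(out / "profiles.tsv", sep="\t")
        sched = pd.DataFrame(
            schedule.cycles, columns=["cycle", "interphase_min", "mitosis_min"]
        )
        sched.to_csv(out / "schedule.tsv", sep="\t", index=False)
    return bundle
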
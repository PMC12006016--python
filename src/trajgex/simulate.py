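"""Synthetic longitudinal PBMC expression data with known ground truth.

Emulates a birth-cohort design in which each child is scheduled for a blood
draw every 3 months from age 3 to 36 months, with heavy visit missingness.
Each gene follows one of six trajectory archetypes (plus a null class) on the
log2 scale, on top of a subject-specific baseline offset, a sex shift, a
seasonal shift and i.i.d. Gaussian noise:

    y_gis = baseline_g + amplitude_g * curve_g(age_is)
            + b_i + sex(i) + season(i, age_is) + eps_gis

The generator returns the expression matrix together with sample metadata,
a gene annotation table (genomic coordinates plus disease-set and MHC-region
membership flags) and the ground-truth archetype labels, so that every
downstream stage of the pipeline can be validated against planted signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARCHETYPES",
    "DYNAMIC_ARCHETYPES",
    "SimulationConfig",
    "SimulatedDataset",
    "archetype_curve",
    "simulate_dataset",
    "study_scale_config",
]

#: Trajectory shape classes. The first six mirror the major trajectory
#: clusters seen in early-childhood PBMC time courses (decreasing, U-shaped,
#: increasing, inverted-U, stable, late rise); NULL genes have no age effect
#: at all and differ from STABLE only in intent (STABLE is a planted,
#: flat "shape", NULL is background).
ARCHETYPES = (
    "DECREASING",
    "U",
    "INCREASING",
    "INVERTED_U",
    "STABLE",
    "LATE_RISE",
    "NULL",
)

#: Archetypes whose unit curve has nonzero peak-to-trough range.
DYNAMIC_ARCHETYPES = ("DECREASING", "U", "INCREASING", "INVERTED_U", "LATE_RISE")

_SEASONS = ("winter", "spring", "summer", "autumn")
# additive shift per season in units of season_amplitude
_SEASON_SHIFT = {"winter": 1.0, "spring": 0.0, "summer": -1.0, "autumn": 0.0}
_MONTH_TO_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}
_HLA_GENOTYPES = ("DR3/DR4", "DR4/DR4", "DR3/DR3", "DR4/x")
_HLA_PROBS = (0.4, 0.3, 0.2, 0.1)

#: MHC region on chromosome 6 (1-based inclusive, Hg38 coordinates).
MHC_CHROM = "chr6"
MHC_START = 28_510_120
MHC_END = 33_480_577


def _default_props() -> dict[str, float]:
    # 10% dynamic overall, spread evenly over the six planted shapes.
    d = {a: 0.1 / 6 for a in ARCHETYPES[:6]}
    d["NULL"] = 0.9
    return d


@dataclass
class SimulationConfig:
    """Parameters of the synthetic longitudinal design.

    Defaults give a desk-scale dataset: 40 subjects scheduled for 12
    three-monthly visits with 50% retention and 2000 genes.  All effect
    sizes are on the log2 scale.
    """

    n_subjects: int = 40
    visit_ages: tuple[float, ...] = tuple(float(a) for a in range(3, 37, 3))
    retention_prob: float = 0.5
    n_genes: int = 2000
    archetype_props: dict[str, float] = field(default_factory=_default_props)
    amplitude_log2: float = 1.0
    subject_sd: float = 0.5
    sex_effect: float = 0.1
    season_amplitude: float = 0.1
    residual_sd: float = 0.5
    frac_t1d_genes: float = 0.01
    frac_mhc_genes: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.visit_ages = tuple(float(a) for a in self.visit_ages)
        if any(b <= a for a, b in zip(self.visit_ages, self.visit_ages[1:])):
            raise ValueError("visit_ages must be strictly increasing")
        if not self.visit_ages:
            raise ValueError("visit_ages must be non-empty")
        if not (0.0 < self.retention_prob <= 1.0):
            raise ValueError("retention_prob must be in (0, 1]")
        for name in ("subject_sd", "residual_sd", "amplitude_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.archetype_props) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in proportions: {sorted(unknown)}")
        total = sum(self.archetype_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_props must sum to 1, got {total}")
        if self.n_subjects < 1 or self.n_genes < 1:
            raise ValueError("n_subjects and n_genes must be positive")


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    expression: pd.DataFrame  # genes x samples, log2 scale
    samples: pd.DataFrame  # sample_id index; subject_id, age_months, sex, season, hla
    annotation: pd.DataFrame  # gene_id index; chrom, start, end, is_t1d, is_mhc
    truth: pd.DataFrame  # gene_id index; archetype, is_dynamic, amplitude_log2
    config: SimulationConfig


def study_scale_config(**overrides) -> SimulationConfig:
    """Configuration matching the real cohort scale: 108 children scheduled
    every 3 months from 3 to 36 months; retention tuned so the expected
    sample count is ~395 (395 / (108 * 12) ~= 0.305)."""
    params = dict(n_subjects=108, retention_prob=395 / (108 * 12))
    params.update(overrides)
    return SimulationConfig(**params)


def archetype_curve(label: str, age, age_range: tuple[float, float]) -> np.ndarray:
    """Unit-scaled log2 deviation of an archetype at ``age``.

    Values lie in [0, 1] before amplitude scaling.  DECREASING is 1 at the
    lower end of ``age_range`` and 0 at the upper end; INCREASING is the
    mirror image.  U is a symmetric quadratic with minimum 0 at the interior
    midpoint and value 1 at both endpoints; INVERTED_U is its mirror.
    STABLE and NULL are identically 0.  LATE_RISE stays at 0 over the first
    two thirds of the range and then rises linearly to 1.
    """
    lo, hi = float(age_range[0]), float(age_range[1])
    if hi <= lo:
        raise ValueError("age_range must satisfy min < max")
    age = np.asarray(age, dtype=float)
    if np.any(age < lo - 1e-9) or np.any(age > hi + 1e-9):
        raise ValueError("age outside age_range")
    t = (age - lo) / (hi - lo)
    if label == "DECREASING":
        out = 1.0 - t
    elif label == "INCREASING":
        out = t
    elif label == "U":
        out = (2.0 * t - 1.0) ** 2
    elif label == "INVERTED_U":
        out = 1.0 - (2.0 * t - 1.0) ** 2
    elif label in ("STABLE", "NULL"):
        out = np.zeros_like(t)
    elif label == "LATE_RISE":
        out = np.clip((t - 2.0 / 3.0) / (1.0 / 3.0), 0.0, 1.0)
    else:
        raise ValueError(f"unknown archetype label: {label!r}")
    return out


def _apportion(props: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over archetypes."""
    labels = [a for a in ARCHETYPES if props.get(a, 0.0) > 0]
    raw = np.array([props[a] * n for a in labels])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(labels, counts))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one longitudinal dataset. Identical config => identical output."""
    rng = np.random.default_rng(config.seed)
    n_sub, ages = config.n_subjects, np.array(config.visit_ages)
    age_range = (float(ages[0]), float(ages[-1]))

    subj_ids = [f"S{i + 1:03d}" for i in range(n_sub)]
    subj_sex = rng.choice(["F", "M"], size=n_sub)
    subj_hla = rng.choice(_HLA_GENOTYPES, size=n_sub, p=_HLA_PROBS)
    subj_birth_month = rng.integers(1, 13, size=n_sub)

    # Bernoulli visit retention; a subject losing every visit keeps one
    # (uniformly chosen) so the random intercept stays identifiable.
    kept = rng.random((n_sub, len(ages))) < config.retention_prob
    for i in range(n_sub):
        if not kept[i].any():
            kept[i, rng.integers(0, len(ages))] = True

    rows = []
    for i, sid in enumerate(subj_ids):
        for j, age in enumerate(ages):
            if not kept[i, j]:
                continue
            month = (int(subj_birth_month[i]) - 1 + int(round(age))) % 12 + 1
            rows.append(
                {
                    "sample_id": f"{sid}_m{int(round(age)):02d}",
                    "subject_id": sid,
                    "age_months": age,
                    "sex": subj_sex[i],
                    "season": _MONTH_TO_SEASON[month],
                    "hla": subj_hla[i],
                }
            )
    samples = pd.DataFrame(rows).set_index("sample_id")
    n_samp = len(samples)

    # gene-level truth
    counts = _apportion(config.archetype_props, config.n_genes)
    labels = np.repeat(list(counts), list(counts.values()))
    rng.shuffle(labels)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    curve_range = {a: (1.0 if a in DYNAMIC_ARCHETYPES else 0.0) for a in ARCHETYPES}
    amp = np.array([config.amplitude_log2 * curve_range[a] for a in labels])
    truth = pd.DataFrame(
        {
            "archetype": labels,
            "amplitude_log2": amp,
            "is_dynamic": amp >= np.log2(1.10),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    annotation = _make_annotation(gene_ids, config, rng)

    baseline = rng.uniform(6.0, 12.0, size=config.n_genes)
    # inter-individual offsets are drawn per gene: each gene has its own
    # pattern of subject-to-subject variation, as in real expression data
    subj_intercept = rng.normal(0.0, config.subject_sd, size=(config.n_genes, n_sub))
    subj_idx = samples["subject_id"].map({s: i for i, s in enumerate(subj_ids)}).to_numpy()
    sample_eff = (
        np.where(samples["sex"].to_numpy() == "F", config.sex_effect, 0.0)
        + config.season_amplitude
        * samples["season"].map(_SEASON_SHIFT).to_numpy()
    )
    age_vec = samples["age_months"].to_numpy()
    curves = {a: archetype_curve(a, age_vec, age_range) for a in counts}
    shape = np.vstack([curves[a] for a in labels])  # genes x samples

    expr = (
        baseline[:, None]
        + config.amplitude_log2 * shape
        + subj_intercept[:, subj_idx]
        + sample_eff[None, :]
        + rng.normal(0.0, config.residual_sd, size=(config.n_genes, n_samp))
    )
    expression = pd.DataFrame(
        expr, index=pd.Index(gene_ids, name="gene_id"), columns=samples.index
    )
    return SimulatedDataset(expression, samples, annotation, truth, dataclasses.replace(config))


def _make_annotation(gene_ids, config: SimulationConfig, rng) -> pd.DataFrame:
    n = len(gene_ids)
    n_mhc = int(round(config.frac_mhc_genes * n))
    n_t1d = int(round(config.frac_t1d_genes * n))
    if n_mhc + n_t1d > n:
        raise ValueError("flagged gene fractions exceed the gene count")
    perm = rng.permutation(n)
    mhc_idx = set(perm[:n_mhc])
    # T1D susceptibility genes overlap the MHC region in reality; let the
    # flag be drawn independently of region membership.
    t1d_idx = set(rng.permutation(n)[:n_t1d])

    chroms, starts, ends = [], [], []
    for i in range(n):
        if i in mhc_idx:
            chrom = MHC_CHROM
            start = int(rng.integers(MHC_START, MHC_END - 10_000))
        else:
            chrom = f"chr{rng.integers(1, 23)}"
            start = int(rng.integers(1, 200_000_000))
        length = int(rng.integers(1_000, 100_000))
        chroms.append(chrom)
        starts.append(start)
        ends.append(start + length)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "is_t1d": [i in t1d_idx for i in range(n)],
            "is_mhc": [i in mhc_idx for i in range(n)],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
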
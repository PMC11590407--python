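"""Synthetic sponge-microbiome perturbation experiment.

Emulates the community structure of a low-microbial-abundance (LMA) sponge
under a specialist-phage disturbance: a single dominant symbiont (~43-54%
relative abundance), a large tail of rare residents (<1% each), seawater
transients that wash out within 24-72 h, the phage's target taxon staying
below 1%, and an opportunist that blooms from ~0.4% to ~13% of the
community only under phage treatment. The design is repeated measures: six
host individuals, each split across five treatments (one untreated control,
CON, and four phage applications), biopsied at 0, 24 and 72 h.

Counts are Dirichlet-multinomial: a sample's expected composition is the
role-multiplied baseline, its realized composition a Dirichlet draw with
concentration theta * p (theta controls overdispersion between replicate
samples), and its reads a multinomial draw at a log-normal library size
truncated below at the minimum retained depth.

Culturable bacterial load (CFU plate counts) is simulated on the log10
scale as a per-treatment linear trend over time with a random per-individual
intercept and residual plate noise, three plates per sample.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CountTable, write_count_table, write_metadata

__all__ = [
    "ROLES",
    "CommunityTemplate",
    "ExperimentDesign",
    "GrowthParams",
    "SyntheticDataset",
    "build_template",
    "default_design",
    "default_growth_params",
    "simulate_experiment",
    "simulate_cfu",
]

ROLES = ("symbiont", "phage_target", "opportunist", "transient", "rare")

#: Expected community share of each structured role per (treatment class,
#: timepoint in hours). The rare tail fills the remainder. The phage-class
#: opportunist bloom (0.004 -> 0.13) and symbiont trajectory (0.43 -> ~0.53
#: -> 0.42) mirror the relative-abundance shifts reported for a phage-
#: disturbed sponge microbiome; the control opportunist reaches only 0.03.
_DEFAULT_SHARES: dict[tuple[str, float], dict[str, float]] = {
    ("control", 0): {"symbiont": 0.43, "opportunist": 0.004, "phage_target": 0.005, "transient": 0.14},
    ("control", 24): {"symbiont": 0.54, "opportunist": 0.004, "phage_target": 0.005, "transient": 0.04},
    ("control", 72): {"symbiont": 0.52, "opportunist": 0.03, "phage_target": 0.005, "transient": 0.02},
    ("phage", 0): {"symbiont": 0.43, "opportunist": 0.004, "phage_target": 0.005, "transient": 0.14},
    ("phage", 24): {"symbiont": 0.53, "opportunist": 0.004, "phage_target": 0.005, "transient": 0.045},
    ("phage", 72): {"symbiont": 0.42, "opportunist": 0.13, "phage_target": 0.005, "transient": 0.02},
}

# Baseline split of the transient (seawater) share across named taxa,
# patterned on ubiquitous aquatic groups (NS5/NS3a/NS4/OM43/SAR86-like).
_TRANSIENT_SPLIT = (0.048, 0.018, 0.013, 0.044, 0.017)

_DEFAULT_N_RARE = 150
_RARE_GEOMETRIC_RATIO = 0.97


@dataclass(frozen=True)
class TaxonRole:
    taxon_id: str
    role: str
    baseline_proportion: float


@dataclass
class CommunityTemplate:
    """Taxon roles, baseline proportions and role multipliers.

    ``multipliers[(role, treatment_class, timepoint_h)]`` scales the
    baseline proportion of every taxon of that role; the scaled vector is
    renormalized to sum to 1. ``theta`` is the Dirichlet concentration mass
    (larger = less overdispersed). The library-size model is log-normal in
    log10 units, truncated below at ``min_depth``.
    """

    taxa: list[TaxonRole]
    multipliers: dict[tuple[str, str, float], float]
    theta: float = 200.0
    library_log10_mean: float = 4.3
    library_log10_sd: float = 0.25
    min_depth: int = 5400

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")
        if self.library_log10_sd < 0:
            raise ValueError("library_log10_sd must be >= 0")
        for t in self.taxa:
            if t.role not in ROLES:
                raise ValueError(f"unknown role {t.role!r} for taxon {t.taxon_id!r}")
            if t.baseline_proportion <= 0:
                raise ValueError(
                    f"baseline proportion for {t.taxon_id!r} must be positive"
                )
        total = sum(t.baseline_proportion for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"baseline proportions sum to {total}, expected 1")
        for key, m in self.multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier {key} must be positive, got {m}")

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    def roles_of(self, role: str) -> list[str]:
        return [t.taxon_id for t in self.taxa if t.role == role]

    def expected_proportions(self, treatment_class: str, timepoint_h: float) -> np.ndarray:
        """Renormalized baseline x multiplier composition for a condition."""
        p = np.array(
            [
                t.baseline_proportion
                * self.multipliers.get((t.role, treatment_class, timepoint_h), 1.0)
                for t in self.taxa
            ]
        )
        return p / p.sum()

    def expected_role_share(self, role: str, treatment_class: str, timepoint_h: float) -> float:
        p = self.expected_proportions(treatment_class, timepoint_h)
        mask = np.array([t.role == role for t in self.taxa])
        return float(p[mask].sum())

    def to_dict(self) -> dict:
        return {
            "taxa": [asdict(t) for t in self.taxa],
            "multipliers": {
                f"{role}|{cls}|{tp}": m for (role, cls, tp), m in self.multipliers.items()
            },
            "theta": self.theta,
            "library_log10_mean": self.library_log10_mean,
            "library_log10_sd": self.library_log10_sd,
            "min_depth": self.min_depth,
        }


_TEMPLATE_SCALARS = {
    "theta",
    "library_log10_mean",
    "library_log10_sd",
    "min_depth",
    "n_rare",
}


def build_template(overrides: dict | None = None) -> CommunityTemplate:
    """Build the default community template, with optional overrides.

    Recognized override keys: the scalars ``theta``, ``library_log10_mean``,
    ``library_log10_sd``, ``min_depth``, ``n_rare``, plus ``baseline`` (a
    mapping from one of the singleton roles ``symbiont`` / ``opportunist`` /
    ``phage_target`` or ``transient`` to its total baseline share) and
    ``shares`` (a mapping ``(treatment_class, timepoint_h) -> {role: share}``
    updating the expected role shares). Unknown keys or roles raise
    ``ValueError``.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _TEMPLATE_SCALARS - {"baseline", "shares"}
    if unknown:
        raise ValueError(f"unknown template override(s): {sorted(unknown)}")

    shares = {k: dict(v) for k, v in _DEFAULT_SHARES.items()}
    baseline_over = overrides.pop("baseline", {})
    for role, value in baseline_over.items():
        if role not in ("symbiont", "opportunist", "phage_target", "transient"):
            raise ValueError(f"unknown role {role!r} in baseline override")
        if value <= 0:
            raise ValueError(f"baseline share for {role!r} must be positive")
        for cls in ("control", "phage"):
            shares[(cls, 0)][role] = value
    for key, role_shares in overrides.pop("shares", {}).items():
        if tuple(key) not in shares:
            raise ValueError(f"unknown (treatment_class, timepoint) {key!r}")
        for role, value in role_shares.items():
            if role not in ("symbiont", "opportunist", "phage_target", "transient"):
                raise ValueError(f"unknown role {role!r} in shares override")
            if value <= 0:
                raise ValueError(f"share for {role!r} must be positive")
            shares[tuple(key)][role] = value

    n_rare = int(overrides.pop("n_rare", _DEFAULT_N_RARE))
    if n_rare < 1:
        raise ValueError("n_rare must be >= 1")

    base = shares[("control", 0)]
    structured = base["symbiont"] + base["opportunist"] + base["phage_target"] + base["transient"]
    rare_total = 1.0 - structured
    if rare_total <= 0:
        raise ValueError("structured role shares leave no room for the rare tail")

    taxa: list[TaxonRole] = [
        TaxonRole("symbiont_halichondribacter", "symbiont", base["symbiont"]),
        TaxonRole("opportunist_vibrio", "opportunist", base["opportunist"]),
        TaxonRole("target_maribacter", "phage_target", base["phage_target"]),
    ]
    split = np.array(_TRANSIENT_SPLIT)
    split = split / split.sum() * base["transient"]
    for i, w in enumerate(split, start=1):
        taxa.append(TaxonRole(f"transient_{i:02d}", "transient", float(w)))
    # frozen geometric rare tail: reproducible "rare biosphere"
    weights = _RARE_GEOMETRIC_RATIO ** np.arange(n_rare)
    weights = weights / weights.sum() * rare_total
    for i, w in enumerate(weights, start=1):
        taxa.append(TaxonRole(f"rare_{i:03d}", "rare", float(w)))
    # absorb float rounding into the largest rare taxon so the sum is exact
    deficit = 1.0 - sum(t.baseline_proportion for t in taxa)
    first_rare = next(i for i, t in enumerate(taxa) if t.role == "rare")
    taxa[first_rare] = TaxonRole(
        taxa[first_rare].taxon_id,
        "rare",
        taxa[first_rare].baseline_proportion + deficit,
    )

    multipliers: dict[tuple[str, str, float], float] = {}
    for (cls, tp), role_shares in shares.items():
        structured_t = sum(role_shares[r] for r in ("symbiont", "opportunist", "phage_target", "transient"))
        rare_t = 1.0 - structured_t
        if rare_t <= 0:
            raise ValueError(f"role shares at ({cls}, {tp}) leave no rare share")
        for role in ("symbiont", "opportunist", "phage_target", "transient"):
            multipliers[(role, cls, float(tp))] = role_shares[role] / base[role]
        multipliers[("rare", cls, float(tp))] = rare_t / rare_total

    scalars = {k: overrides[k] for k in overrides}
    return CommunityTemplate(taxa=taxa, multipliers=multipliers, **scalars)


@dataclass
class ExperimentDesign:
    """Repeated-measures layout: every (individual, treatment) pair is
    sampled at every timepoint."""

    individuals: list[str] = field(
        default_factory=lambda: [f"sponge{i}" for i in range(1, 7)]
    )
    treatments: list[str] = field(
        default_factory=lambda: ["CON", "INJ-HI", "INJ-LO", "SUS-HI", "SUS-LO"]
    )
    reference: str = "CON"
    timepoints_h: list[float] = field(default_factory=lambda: [0, 24, 72])

    def __post_init__(self) -> None:
        if not self.individuals or not self.treatments or not self.timepoints_h:
            raise ValueError("design must have individuals, treatments and timepoints")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatment labels must be unique")
        if self.reference not in self.treatments:
            raise ValueError(f"reference {self.reference!r} not among treatments")

    def treatment_class(self, treatment: str) -> str:
        return "control" if treatment == self.reference else "phage"

    def samples(self):
        """Yield (sample_id, individual, treatment, timepoint_h) rows."""
        for ind in self.individuals:
            for trt in self.treatments:
                for tp in self.timepoints_h:
                    yield f"{ind}_{trt}_t{tp:g}", ind, trt, float(tp)


def default_design() -> ExperimentDesign:
    return ExperimentDesign()


@dataclass
class GrowthParams:
    """Log-linear CFU growth model: log10 CFU = intercept_i + beta_t * t + eps.

    Slopes are log10 CFU per hour. The printed control/phage slopes (CON
    0.004, INJ-LO 0.023, SUS-HI 0.009) bracket the invented INJ-HI (0.015)
    and SUS-LO (0.012) defaults. The intercept scale (log10 CFU at 0 h) is a
    conventional choice; absolute plate-count magnitudes are not modeled on
    any reported value.
    """

    slopes: dict[str, float] = field(
        default_factory=lambda: {
            "CON": 0.004,
            "INJ-HI": 0.015,
            "INJ-LO": 0.023,
            "SUS-HI": 0.009,
            "SUS-LO": 0.012,
        }
    )
    intercept_mean: float = 3.5
    intercept_sd: float = 0.2
    residual_sd: float = 0.15
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def default_growth_params() -> GrowthParams:
    return GrowthParams()


@dataclass
class SyntheticDataset:
    counts: CountTable
    metadata: pd.DataFrame
    cfu: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": out / "counts.tsv",
            "metadata": out / "metadata.tsv",
            "cfu": out / "cfu.tsv",
            "truth": out / "truth.json",
        }
        write_count_table(self.counts, paths["counts"])
        write_metadata(self.metadata, paths["metadata"])
        self.cfu.to_csv(paths["cfu"], sep="\t", index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        return {k: str(v) for k, v in paths.items()}


def _draw_library_size(rng: np.random.Generator, template: CommunityTemplate) -> int:
    """Truncated log-normal library size (resampled below min_depth)."""
    for _ in range(1000):
        depth = int(round(10 ** rng.normal(template.library_log10_mean, template.library_log10_sd)))
        if depth >= template.min_depth:
            return depth
    return template.min_depth


def simulate_experiment(
    template: CommunityTemplate,
    design: ExperimentDesign,
    seed: int,
    growth_params: GrowthParams | None = None,
) -> SyntheticDataset:
    """Draw a full synthetic dataset (counts, metadata, CFU) for a design.

    Identical (template, design, seed) yield byte-identical outputs.
    """
    rows = list(design.samples())
    if not rows:
        raise ValueError("empty design")
    ss = np.random.SeedSequence(seed)
    counts_seed, cfu_seed = ss.spawn(2)
    rng = np.random.default_rng(counts_seed)

    expected = {
        (cls, tp): template.expected_proportions(cls, tp)
        for cls in ("control", "phage")
        for tp in {float(t) for t in design.timepoints_h}
    }
    columns = {}
    meta_rows = []
    for sample_id, ind, trt, tp in rows:
        p = expected[(design.treatment_class(trt), tp)]
        composition = rng.dirichlet(template.theta * p)
        depth = _draw_library_size(rng, template)
        columns[sample_id] = rng.multinomial(depth, composition)
        meta_rows.append((sample_id, ind, trt, tp))

    counts = CountTable(
        pd.DataFrame(columns, index=pd.Index(template.taxon_ids, name="taxon_id")),
        unit="counts",
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "individual", "treatment", "timepoint_h"]
    ).set_index("sample_id")

    growth_params = growth_params or default_growth_params()
    cfu = simulate_cfu(design, growth_params, seed=int(cfu_seed.generate_state(1)[0] % (2**31)))
    truth = {
        "seed": seed,
        "template": template.to_dict(),
        "growth_params": {
            "slopes": growth_params.slopes,
            "intercept_mean": growth_params.intercept_mean,
            "intercept_sd": growth_params.intercept_sd,
            "residual_sd": growth_params.residual_sd,
        },
    }
    return SyntheticDataset(counts=counts, metadata=metadata, cfu=cfu, truth=truth)


def simulate_cfu(design: ExperimentDesign, params: GrowthParams, seed: int) -> pd.DataFrame:
    """Simulate triplicate plate counts per sample under log-linear growth.

    Returns a table with columns sample_id, individual, treatment,
    timepoint_h, replicate, cfu_count; counts are integers >= 0 on the
    linear scale.
    """
    rng = np.random.default_rng(seed)
    missing = set(design.treatments) - set(params.slopes)
    if missing:
        raise ValueError(f"no growth slope for treatment(s): {sorted(missing)}")
    intercepts = {
        ind: rng.normal(params.intercept_mean, params.intercept_sd)
        for ind in design.individuals
    }
    rows = []
    for sample_id, ind, trt, tp in design.samples():
        mean_log10 = intercepts[ind] + params.slopes[trt] * tp
        for rep in range(1, params.n_replicates + 1):
            log10_cfu = mean_log10 + rng.normal(0.0, params.residual_sd)
            rows.append((sample_id, ind, trt, tp, rep, max(0, int(round(10**log10_cfu)))))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "individual", "treatment", "timepoint_h", "replicate", "cfu_count"],
    )
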
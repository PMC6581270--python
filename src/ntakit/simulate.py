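"""Synthetic NTA experiments with known ground truth.

The generator emulates a hierarchical NTA study: treatment groups, each
with several biological samples (animals); each sample is diluted once,
loaded into the instrument by independent syringe injections, and each
injection is measured by several 30-second videos (technical
replicates).  The bundled "study" design mirrors a murine pregnancy
time course: 6 groups totalling 37 biological samples, 2 injections x
3 technical videos each, i.e. 222 distinct measurements.

Generative model
----------------
* per biological sample: latent total concentration ~ lognormal around
  the group mean with coefficient of variation ``cv_biological``;
* per injection and per technical video: independent multiplicative
  lognormal factors with ``cv_injection`` / ``cv_technical``, each with
  mean 1 so replicate averaging is unbiased;
* particle-size distribution: a lognormal with a given mode (nm) and
  geometric standard deviation, discretized onto the bin grid and
  normalized to the grid's mass;
* the emitted file holds the DILUTED per-bin concentrations (divided by
  the per-sample fold dilution), so the pipeline's back-calculation is
  exercised end to end.

Noise is multiplicative because particle concentrations are positive
and instrument variability scales with the signal; the generator does
not model Brownian tracking, camera level or detection threshold.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SchemaError
from .ntaio import AcquisitionMeta, WideExperimentTable, combine_experiments, \
    write_experiment_summary
from .summarize import nanocount, nanolyze
from .tidier import SampleNameSchema, tidy_table

__all__ = [
    "GroupSpec",
    "SimulationDesign",
    "GroundTruth",
    "STUDY_SCHEMA",
    "study_design",
    "load_design",
    "simulate_experiment",
    "recovery_report",
]

#: Measurement names are group_sample_dilution_injection_techrep.
STUDY_SCHEMA = SampleNameSchema(
    field_names=("group", "sample", "dilution", "injection", "tech_rep"),
    separator="_",
    dilution_field="dilution",
)

_INJECTION_LABELS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group of the simulated study."""

    label: str
    n_biological: int
    mean_total_concentration: float  # particles/mL, undiluted
    size_mode: float = 100.0  # nm, mode of the lognormal size distribution
    size_gsd: float = 1.4  # geometric standard deviation, > 1

    def __post_init__(self) -> None:
        if self.n_biological < 1:
            raise ValueError(f"group {self.label!r}: n_biological must be >= 1")
        if not self.mean_total_concentration > 0:
            raise ValueError(f"group {self.label!r}: mean concentration must be > 0")
        if not self.size_mode > 0 or not self.size_gsd > 1:
            raise ValueError(f"group {self.label!r}: need size_mode > 0, size_gsd > 1")
        if "_" in self.label:
            raise ValueError(f"group label {self.label!r} may not contain '_'")


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of a simulated NTA experiment."""

    groups: tuple[GroupSpec, ...]
    n_injections: int = 2
    n_technical: int = 3
    dilutions: tuple[float, ...] = (125.0, 250.0, 500.0)
    cv_biological: float = 0.25
    cv_injection: float = 0.05
    cv_technical: float = 0.10
    bin_width: float = 1.0
    size_min: float = 0.0
    size_max: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "dilutions", tuple(float(d) for d in self.dilutions))
        if not self.groups:
            raise ValueError("design needs at least one group")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate group labels: {labels}")
        if self.n_injections < 1 or self.n_technical < 1:
            raise ValueError("n_injections and n_technical must be >= 1")
        if self.n_injections > len(_INJECTION_LABELS):
            raise ValueError(f"at most {len(_INJECTION_LABELS)} injections supported")
        if not self.dilutions or any(d <= 0 for d in self.dilutions):
            raise ValueError("dilutions must be positive fold factors")
        for cv in (self.cv_biological, self.cv_injection, self.cv_technical):
            if cv < 0:
                raise ValueError("coefficients of variation must be >= 0")

    @property
    def n_biological(self) -> int:
        return sum(g.n_biological for g in self.groups)

    @property
    def n_measurements(self) -> int:
        return self.n_biological * self.n_injections * self.n_technical

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            software_version="3.2",
            bin_width=self.bin_width,
            size_min=self.size_min,
            size_max=self.size_max,
            extra=(("Instrument", "synthetic"),),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Latent values behind a simulated experiment.

    ``samples`` has one row per biological sample (group, sample,
    dilution, true_total — the latent undiluted total concentration);
    ``measurements`` has one row per video with its realized expected
    total after injection/technical noise; ``expected_curves`` holds
    the undiluted expected per-bin curve, bins x measurements, whose
    column sums equal ``measurements.true_total`` exactly.
    """

    samples: pd.DataFrame
    measurements: pd.DataFrame
    group_means: pd.DataFrame
    bin_centers: np.ndarray
    expected_curves: np.ndarray


def study_design(seed: int = 0) -> SimulationDesign:
    """The bundled pregnancy-time-course design: 6 groups, 37 samples,
    2 injections x 3 technical videos = 222 measurements.

    Group means rise across gestation, peak at GD14.5 and fall after
    delivery — the qualitative pattern the toolkit's demo analyses.
    """
    return SimulationDesign(
        groups=(
            GroupSpec("NP", 7, 2.0e10),
            GroupSpec("GD5.5", 6, 3.0e10),
            GroupSpec("GD10.5", 6, 4.0e10),
            GroupSpec("GD14.5", 6, 6.0e10),
            GroupSpec("GD17.5", 6, 5.5e10),
            GroupSpec("PP1", 6, 4.0e10),
        ),
        seed=seed,
    )


def load_design(path=None) -> SimulationDesign:
    """Read a :class:`SimulationDesign` from a TOML file.

    With no path, loads the bundled study configuration."""
    if path is None:
        text = resources.files("ntakit").joinpath("configs/study.toml").read_text()
        cfg = tomllib.loads(text)
    else:
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    groups = tuple(GroupSpec(**g) for g in cfg.pop("groups"))
    return SimulationDesign(groups=groups, **cfg)


def _ln_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 lognormal multiplicative factors with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=n))


def _size_probabilities(centers: np.ndarray, width: float,
                        mode: float, gsd: float) -> np.ndarray:
    """Lognormal size mass per bin, normalized to the grid."""
    sigma = np.log(gsd)
    mu = np.log(mode) + sigma * sigma  # mode = exp(mu - sigma^2)
    lo = np.maximum(centers - width / 2.0, 0.0)
    hi = centers + width / 2.0
    dist = sps.lognorm(s=sigma, scale=np.exp(mu))
    mass = dist.cdf(hi) - dist.cdf(lo)
    return mass / mass.sum()


def simulate_experiment(
    design: SimulationDesign,
    out_dir=None,
) -> tuple[WideExperimentTable, GroundTruth]:
    """Draw one experiment from the design.

    Returns the combined wide table and its ground truth.  When
    ``out_dir`` is given, also writes one experiment-summary CSV per
    group (plus ``ground_truth_samples.csv``) there; identical seeds
    produce byte-identical files.
    """
    rng = np.random.default_rng(design.seed)
    meta = design.meta()
    centers = meta.bin_centers()

    sample_rows, meas_rows, curves, group_tables = [], [], [], []
    for g in design.groups:
        probs = _size_probabilities(centers, design.bin_width, g.size_mode, g.size_gsd)
        bio = g.mean_total_concentration * _ln_factors(
            rng, design.cv_biological, g.n_biological
        )
        names, cols = [], []
        for b in range(g.n_biological):
            sample = f"M{b + 1}"
            # deterministic cycling keeps measurement names seed-independent
            dilution = design.dilutions[b % len(design.dilutions)]
            sample_rows.append(
                {"group": g.label, "sample": sample, "dilution": dilution,
                 "true_total": bio[b]}
            )
            inj_f = _ln_factors(rng, design.cv_injection, design.n_injections)
            for i in range(design.n_injections):
                tech_f = _ln_factors(rng, design.cv_technical, design.n_technical)
                for t in range(design.n_technical):
                    total = bio[b] * inj_f[i] * tech_f[t]
                    dil_token = (
                        str(int(dilution)) if dilution == int(dilution)
                        else str(dilution)
                    )
                    name = (
                        f"{g.label}_{sample}_{dil_token}_"
                        f"{_INJECTION_LABELS[i]}_{t + 1}"
                    )
                    curve = total * probs
                    names.append(name)
                    cols.append(curve / dilution)  # instrument sees diluted sample
                    curves.append(curve)
                    meas_rows.append(
                        {"name": name, "group": g.label, "sample": sample,
                         "injection": _INJECTION_LABELS[i], "tech_rep": t + 1,
                         "dilution": dilution, "true_total": total}
                    )
        group_tables.append(
            WideExperimentTable(
                meta=meta, bin_centers=centers,
                measurement_names=tuple(names),
                counts=np.column_stack(cols),
            )
        )

    table = combine_experiments(group_tables) if len(group_tables) > 1 else group_tables[0]
    truth = GroundTruth(
        samples=pd.DataFrame(sample_rows),
        measurements=pd.DataFrame(meas_rows),
        group_means=pd.DataFrame(
            {"group": [g.label for g in design.groups],
             "mean_total": [g.mean_total_concentration for g in design.groups]}
        ),
        bin_centers=centers,
        expected_curves=np.column_stack(curves),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for g, t in zip(design.groups, group_tables):
            write_experiment_summary(t, out_dir / f"{g.label}.csv")
        truth.samples.to_csv(out_dir / "ground_truth_samples.csv", index=False)
    return table, truth


def recovery_report(
    table: WideExperimentTable,
    truth: GroundTruth,
    schema: SampleNameSchema = STUDY_SCHEMA,
) -> pd.DataFrame:
    """Run the full pipeline and compare per-sample totals to the truth.

    Pipeline: tidy -> nanolyze over technical replicates -> nanolyze
    over injections -> nanocount per sample.  The standard error per
    sample comes from a one-pass summary of the per-video totals.
    Returns one row per biological sample with columns ``group,
    sample, true, estimated, se, rel_error, within_3se``.
    """
    needed = {"group", "sample", "injection", "tech_rep"}
    if not needed <= set(schema.field_names):
        raise SchemaError(
            f"recovery needs schema fields {sorted(needed)}, got {schema.field_names}"
        )
    tidy = tidy_table(table, schema)
    tech = nanolyze(
        tidy, ["group", "sample", "injection", "particle_size"],
        "true_count", prefix="Tech",
    )
    inj = nanolyze(
        tech, ["group", "sample", "particle_size"], "Tech_mean", prefix="Inj"
    )
    totals = nanocount(inj, ["group", "sample"], "Inj_mean")

    per_video = nanocount(tidy, ["group", "sample", "injection", "tech_rep"],
                          "true_count")
    spread = nanolyze(per_video, ["group", "sample"], "total", prefix="Samp")

    est = totals.merge(spread, on=["group", "sample"])
    est["group"] = est["group"].astype(str)
    report = est.merge(
        truth.samples.assign(group=lambda d: d["group"].astype(str)),
        on=["group", "sample"],
    )
    report = report.rename(columns={"total": "estimated", "true_total": "true",
                                    "Samp_se": "se"})
    report["rel_error"] = (report["estimated"] - report["true"]).abs() / report["true"]
    with np.errstate(invalid="ignore"):
        report["within_3se"] = (
            (report["estimated"] - report["true"]).abs() <= 3.0 * report["se"]
        )
    return report[
        ["group", "sample", "true", "estimated", "se", "rel_error", "within_3se"]
    ]
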
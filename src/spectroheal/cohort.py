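"""Synthetic study cohort: subjects, CPMG decays and FT-IR spectra.

The study design this package analyzes is a three-group comparison on blood
plasma: 20 healthy volunteers measured once, and 10 colorectal-cancer patients
measured preoperatively and again 7 days after tumor resection (paired
``crc_pre`` / ``crc_post`` records).  No raw measurements are distributed, so
this module generates a fully synthetic cohort with the statistical structure
the downstream analysis assumes:

* CPMG decays are multi-exponential with a dominant long-T2 "soluble"
  component and small short/medium-T2 "insoluble" components; surgery shifts
  the soluble peak (pre < post < healthy in the default truth), each subject
  is measured at two echo times (70 and 500 microseconds), and Gaussian noise
  is added at a configurable fraction of the initial amplitude.
* FT-IR spectra are sums of Gaussian bands in the five canonical plasma
  regions; disease and recovery act as group-dependent band-amplitude effects
  (preoperative samples mainly on the amide envelope, postoperative samples
  partly restored and partly displaced onto C-H stretching bands, which is
  what makes the postoperative group a *distinct* region of PC space rather
  than a point on the healthy-preoperative line).
* Subject metadata mirror the published clinical table for the 10 patients;
  volunteer entries are synthetic stubs (only the group's size, age range and
  mean age are published) shipped in ``data/volunteers_synthetic.csv``.

Every random draw descends from the master seed through a splittable
``numpy.random.SeedSequence`` keyed by (seed, subject index, stream), so any
single measurement can be regenerated in isolation and the whole bundle is
bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .ftir import Spectrum, default_axis, gaussian_bands, write_spectrum_csv
from .relaxometry import CPMGDecay

__all__ = [
    "SubjectRecord",
    "CohortConfig",
    "Cohort",
    "load_table1_fixture",
    "simulate_cpmg_decay",
    "simulate_ftir_spectrum",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "DEFAULT_DECAY_COMPONENTS",
    "DEFAULT_BANDS",
]

Group = Literal["healthy", "crc_pre", "crc_post"]


@dataclass
class SubjectRecord:
    subject_id: str
    group: Group
    pair_id: str = ""
    age: float = 0.0
    sex: Literal["F", "M"] = "F"
    stage_after_surgery: str = ""
    extra: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group == "healthy" and self.pair_id:
            raise ValueError(f"{self.subject_id}: healthy records take no pair_id")
        if self.age <= 0:
            raise ValueError(f"{self.subject_id}: age must be positive")


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    try:
        ref = resources.files("spectroheal.data").joinpath(name)
        text = ref.read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise RuntimeError(
            f"packaged fixture {name!r} is missing or unreadable; "
            "the installation is corrupt"
        ) from exc
    rows = list(csv.DictReader(text.splitlines()))
    if not rows:
        raise RuntimeError(f"packaged fixture {name!r} is empty")
    return rows


def load_table1_fixture() -> list[SubjectRecord]:
    """The study cohort's metadata: 20 volunteers + 10 patients (pre and post).

    Patient rows are transcribed from the published clinical table (ages,
    staging, hemogram values and the rest are carried verbatim in ``extra``);
    each patient yields a ``crc_pre`` and a paired ``crc_post`` record.
    Volunteer rows are synthetic stubs consistent with the published summary
    (n = 20, ages 26-65, mean 52).
    """
    records: list[SubjectRecord] = []
    for row in _read_packaged_csv("volunteers_synthetic.csv"):
        records.append(
            SubjectRecord(
                subject_id=row["Volunteer"],
                group="healthy",
                age=float(row["Age (years)"]),
                sex=row["Sex"],  # type: ignore[arg-type]
            )
        )
    for row in _read_packaged_csv("table1_patients.csv"):
        pid = row["Patient"]
        extra = {
            k: v
            for k, v in row.items()
            if k not in {"Patient", "Sex", "Age (years)", "Stage of diagnosis after surgery"}
        }
        common = dict(
            age=float(row["Age (years)"]),
            sex=row["Sex"],
            stage_after_surgery=row["Stage of diagnosis after surgery"],
            extra=extra,
        )
        records.append(SubjectRecord(f"{pid}_pre", "crc_pre", pair_id=pid, **common))
        records.append(SubjectRecord(f"{pid}_post", "crc_post", pair_id=pid, **common))
    _check_pairing(records)
    return records


def _check_pairing(records: Sequence[SubjectRecord]) -> None:
    pre = {r.pair_id for r in records if r.group == "crc_pre"}
    for r in records:
        if r.group == "crc_post":
            n = sum(1 for q in records if q.group == "crc_pre" and q.pair_id == r.pair_id)
            if n != 1:
                raise ValueError(
                    f"{r.subject_id}: pair_id {r.pair_id!r} resolves to {n} "
                    "preoperative records (expected exactly 1)"
                )
    post = {r.pair_id for r in records if r.group == "crc_post"}
    if pre - post:
        raise ValueError(f"preoperative records without postoperative partner: {sorted(pre - post)}")


# ---------------------------------------------------------------------------
# default synthetic truth
# ---------------------------------------------------------------------------

#: per-group decay truth: (T2 ms, fraction).  The soluble (long-T2) peak sits
#: at 550 ms in health, drops to 400 ms preoperatively and recovers partway
#: (480 ms) 7 days after surgery; two small insoluble components are common.
DEFAULT_DECAY_COMPONENTS: dict[str, list[tuple[float, float]]] = {
    "healthy": [(1.5, 0.05), (8.0, 0.10), (550.0, 0.85)],
    "crc_pre": [(1.5, 0.05), (8.0, 0.10), (400.0, 0.85)],
    "crc_post": [(1.5, 0.05), (8.0, 0.10), (480.0, 0.85)],
}

#: shared band truth (center cm^-1, sigma cm^-1, apex absorbance) across the
#: five plasma regions; 10 bands below 1850 and 11 bands in 2700-3800 so the
#: two standard deconvolution windows see exactly their nominal band counts.
_BASE_BANDS: list[tuple[float, float, float]] = [
    # R1 350-1000
    (520.0, 45.0, 0.42),
    (700.0, 60.0, 0.30),
    (900.0, 50.0, 0.18),
    # R2 1000-1500
    (1080.0, 30.0, 0.14),
    (1250.0, 35.0, 0.12),
    (1320.0, 25.0, 0.10),
    (1455.0, 20.0, 0.16),
    # R3 1500-1800 (amide II / amide I / lipid ester)
    (1545.0, 22.0, 0.45),
    (1655.0, 24.0, 0.95),
    (1740.0, 18.0, 0.12),
    # R4 1850-2500 (weak broad feature)
    (2100.0, 120.0, 0.10),
    # R5 2700-3800 (C-H stretches, amide A/B, O-H massif)
    (2760.0, 25.0, 0.10),
    (2850.0, 15.0, 0.22),
    (2898.0, 12.0, 0.15),
    (2940.0, 14.0, 0.30),
    (2985.0, 14.0, 0.14),
    (3045.0, 22.0, 0.12),
    (3120.0, 30.0, 0.22),
    (3205.0, 38.0, 0.55),
    (3300.0, 40.0, 0.85),
    (3430.0, 48.0, 1.00),
    (3572.0, 45.0, 0.40),
]

#: group-dependent amplitude offsets added to the base truth, keyed by band
#: center.  Preoperative disease loads on the amide envelope; the postoperative
#: state recovers only partway along that axis and additionally shifts C-H
#: stretching bands, displacing the group sideways in PC space.
_GROUP_AMPLITUDE_OFFSETS: dict[str, dict[float, float]] = {
    "healthy": {},
    "crc_pre": {1655.0: 0.18, 1545.0: 0.06, 3300.0: 0.10},
    "crc_post": {1655.0: 0.09, 1545.0: 0.03, 3300.0: 0.05, 2940.0: 0.10, 3120.0: 0.06},
}


def _bands_for_group(group: str) -> list[tuple[float, float, float]]:
    off = _GROUP_AMPLITUDE_OFFSETS[group]
    return [(c, s, a + off.get(c, 0.0)) for c, s, a in _BASE_BANDS]


DEFAULT_BANDS: dict[str, list[tuple[float, float, float]]] = {
    g: _bands_for_group(g) for g in ("healthy", "crc_pre", "crc_post")
}


class CohortConfig(BaseModel):
    """Knobs of the synthetic cohort; defaults reproduce the study design."""

    n_healthy: int = Field(20, ge=1)
    n_patients: int = Field(10, ge=1)
    decay_components_by_group: dict[str, list[tuple[float, float]]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_DECAY_COMPONENTS.items()}
    )
    band_effects_by_group: dict[str, list[tuple[float, float, float]]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()}
    )
    te_us: tuple[float, ...] = (70.0, 500.0)
    n_echoes: int = Field(3000, ge=2)
    noise_sd_decay: float = Field(0.002, ge=0)  # fraction of initial amplitude (SNR 500)
    noise_sd_spectrum: float = Field(0.003, ge=0)  # absorbance units
    subject_cv: float = Field(0.02, ge=0)  # between-subject band-amplitude CV
    deproteinized: bool = False
    insoluble_damping: float = Field(0.25, gt=0, le=1)
    seed: int = 0

    @field_validator("decay_components_by_group")
    @classmethod
    def _fractions_sum_to_one(cls, v):
        for g, comps in v.items():
            if any(t2 <= 0 or f <= 0 for t2, f in comps):
                raise ValueError(f"group {g}: T2 values and fractions must be positive")
            total = sum(f for _, f in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {g}: fractions sum to {total}, expected 1")
        return v

    @field_validator("band_effects_by_group")
    @classmethod
    def _bands_positive(cls, v):
        for g, bands in v.items():
            if any(s <= 0 or a < 0 for _, s, a in bands):
                raise ValueError(f"group {g}: widths must be > 0 and amplitudes >= 0")
        return v

    @model_validator(mode="after")
    def _groups_present(self):
        for d in (self.decay_components_by_group, self.band_effects_by_group):
            missing = {"healthy", "crc_pre", "crc_post"} - set(d)
            if missing:
                raise ValueError(f"missing groups {sorted(missing)}")
        return self


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _rng(seed: int | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed))


def simulate_cpmg_decay(
    components: Sequence[tuple[float, float]],
    te_us: float,
    n_echoes: int,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> CPMGDecay:
    """Multi-exponential CPMG forward model plus Gaussian noise.

    ``components`` is a list of (T2 in ms, fraction); fractions must sum to 1
    so the noiseless zero-time amplitude is exactly 1.  Echo k is sampled at
    tau_k = k * te_us.
    """
    if te_us <= 0:
        raise ValueError("te_us must be positive")
    if n_echoes < 2:
        raise ValueError("need at least 2 echoes")
    if any(t2 <= 0 for t2, _ in components):
        raise ValueError("T2 values must be positive")
    fractions = np.array([f for _, f in components], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {fractions.sum()}, expected 1")
    tau = te_us * np.arange(1, n_echoes + 1, dtype=float)
    tau_ms = tau / 1000.0
    M = np.zeros(n_echoes)
    for t2, frac in components:
        M += frac * np.exp(-tau_ms / t2)
    if noise_sd > 0:
        M = M + _rng(seed).normal(0.0, noise_sd, n_echoes)
    return CPMGDecay(
        tau_us=tau,
        M=M,
        te_us=te_us,
        n_echoes=n_echoes,
        noise_sd_estimate=noise_sd if noise_sd > 0 else None,
    )


def simulate_ftir_spectrum(
    bands: Sequence[tuple[float, float, float]],
    axis: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "",
    plasma_kind: Literal["native", "deproteinized"] = "native",
) -> Spectrum:
    """Sum-of-Gaussians absorbance spectrum plus white noise."""
    if axis is None:
        axis = default_axis()
    axis = np.asarray(axis, dtype=float)
    from .ftir import Band

    band_objs = []
    for c, s, a in bands:
        if not (axis[0] <= c <= axis[-1]):
            raise ValueError(f"band center {c} outside axis [{axis[0]}, {axis[-1]}]")
        band_objs.append(Band(c, s, a))
    y = gaussian_bands(axis, band_objs)
    if noise_sd > 0:
        y = y + _rng(seed).normal(0.0, noise_sd, len(axis))
    return Spectrum(axis, y, subject_id=subject_id, plasma_kind=plasma_kind)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    records: list[SubjectRecord]
    decays: dict[tuple[str, float], CPMGDecay]  # (subject_id, te_us) -> decay
    spectra: dict[str, Spectrum]
    config: CohortConfig


# stream codes for the per-subject splittable seeding
_STREAM_DECAY = 0  # + te index
_STREAM_SPECTRUM = 10
_STREAM_SUBJECT = 11


def _subject_records(config: CohortConfig) -> list[SubjectRecord]:
    fixture = load_table1_fixture()
    if config.n_healthy == 20 and config.n_patients == 10:
        return fixture
    # off-design sizes: recycle fixture entries, then synthesize extras
    rng = _rng(np.random.SeedSequence((config.seed, 999_999)))
    records: list[SubjectRecord] = []
    vols = [r for r in fixture if r.group == "healthy"]
    for i in range(config.n_healthy):
        if i < len(vols):
            records.append(vols[i])
        else:
            records.append(
                SubjectRecord(
                    subject_id=f"V{i + 1}",
                    group="healthy",
                    age=float(rng.integers(26, 66)),
                    sex="F" if i % 2 == 0 else "M",
                )
            )
    pres = [r for r in fixture if r.group == "crc_pre"]
    posts = {r.pair_id: r for r in fixture if r.group == "crc_post"}
    for i in range(config.n_patients):
        if i < len(pres):
            records.append(pres[i])
            records.append(posts[pres[i].pair_id])
        else:
            pid = f"P{i + 1}"
            age = float(rng.integers(45, 82))
            sex = "M" if i % 2 == 0 else "F"
            records.append(SubjectRecord(f"{pid}_pre", "crc_pre", pair_id=pid, age=age, sex=sex))
            records.append(SubjectRecord(f"{pid}_post", "crc_post", pair_id=pid, age=age, sex=sex))
    return records


def _damp_insoluble(
    components: Sequence[tuple[float, float]], damping: float
) -> list[tuple[float, float]]:
    """Deproteinization model: insoluble (T2 < 100 ms) amplitudes are damped,
    then fractions renormalized to 1."""
    damped = [(t2, f * (damping if t2 < 100.0 else 1.0)) for t2, f in components]
    total = sum(f for _, f in damped)
    return [(t2, f / total) for t2, f in damped]


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw the full synthetic cohort: metadata, two decays and one spectrum
    per subject record, all reproducible from ``config.seed``."""
    if config is None:
        config = CohortConfig()
    records = _subject_records(config)
    kind: Literal["native", "deproteinized"] = (
        "deproteinized" if config.deproteinized else "native"
    )
    decays: dict[tuple[str, float], CPMGDecay] = {}
    spectra: dict[str, Spectrum] = {}
    for idx, rec in enumerate(records):
        comps = config.decay_components_by_group[rec.group]
        if config.deproteinized:
            comps = _damp_insoluble(comps, config.insoluble_damping)
        for j, te in enumerate(config.te_us):
            decays[(rec.subject_id, te)] = simulate_cpmg_decay(
                comps,
                te_us=te,
                n_echoes=config.n_echoes,
                noise_sd=config.noise_sd_decay,
                seed=np.random.SeedSequence((config.seed, idx, _STREAM_DECAY + j)),
            )
        bands = config.band_effects_by_group[rec.group]
        if config.subject_cv > 0:
            srng = _rng(np.random.SeedSequence((config.seed, idx, _STREAM_SUBJECT)))
            jitter = srng.lognormal(0.0, config.subject_cv, len(bands))
            bands = [(c, s, a * j) for (c, s, a), j in zip(bands, jitter)]
        spectra[rec.subject_id] = simulate_ftir_spectrum(
            bands,
            noise_sd=config.noise_sd_spectrum,
            seed=np.random.SeedSequence((config.seed, idx, _STREAM_SPECTRUM)),
            subject_id=rec.subject_id,
            plasma_kind=kind,
        )
    return Cohort(records=records, decays=decays, spectra=spectra, config=config)


# ---------------------------------------------------------------------------
# directory round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort bundle: subjects.csv + two-column CSVs per measurement."""
    out = Path(out_dir)
    (out / "decays").mkdir(parents=True, exist_ok=True)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    with (out / "subjects.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group", "pair_id", "age", "sex", "stage_after_surgery"])
        for r in cohort.records:
            w.writerow([r.subject_id, r.group, r.pair_id, r.age, r.sex, r.stage_after_surgery])
    for (sid, te), decay in cohort.decays.items():
        path = out / "decays" / f"{sid}_te{te:g}.csv"
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["tau_us", "M"])
            for t, m in zip(decay.tau_us, decay.M):
                w.writerow([f"{t:.10g}", f"{m:.10g}"])
    for sid, spec in cohort.spectra.items():
        write_spectrum_csv(spec, out / "spectra" / f"{sid}.csv")


def read_cohort(in_dir: str | Path, te_us: Sequence[float] = (70.0, 500.0)) -> Cohort:
    """Read a bundle written by :func:`write_cohort` (or assembled by hand)."""
    root = Path(in_dir)
    subjects = root / "subjects.csv"
    if not subjects.exists():
        raise FileNotFoundError(f"{subjects} not found")
    records: list[SubjectRecord] = []
    with subjects.open() as fh:
        for row in csv.DictReader(fh):
            records.append(
                SubjectRecord(
                    subject_id=row["subject_id"],
                    group=row["group"],  # type: ignore[arg-type]
                    pair_id=row.get("pair_id", ""),
                    age=float(row.get("age", 1) or 1),
                    sex=row.get("sex", "F"),  # type: ignore[arg-type]
                    stage_after_surgery=row.get("stage_after_surgery", ""),
                )
            )
    _check_pairing(records)
    decays: dict[tuple[str, float], CPMGDecay] = {}
    spectra: dict[str, Spectrum] = {}
    from .ftir import read_spectrum

    for rec in records:
        for te in te_us:
            path = root / "decays" / f"{rec.subject_id}_te{te:g}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing decay file {path}")
            data = np.genfromtxt(path, delimiter=",", skip_header=1)
            decays[(rec.subject_id, te)] = CPMGDecay(
                tau_us=data[:, 0], M=data[:, 1], te_us=te, n_echoes=len(data)
            )
        spath = root / "spectra" / f"{rec.subject_id}.csv"
        if not spath.exists():
            raise FileNotFoundError(f"missing spectrum file {spath}")
        spectra[rec.subject_id] = read_spectrum(spath, subject_id=rec.subject_id)
    # config is unknown for an external directory; keep defaults as metadata
    return Cohort(records=records, decays=decays, spectra=spectra, config=CohortConfig())
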
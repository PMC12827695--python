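"""Synthetic two-group, multi-site BOLD cohort generator.

Each subject's ROI x T matrix is temporally smooth Gaussian noise plus
community-structured co-fluctuation events: at event frames, drawn by a
renewal process with group-specific mean inter-event interval, a short bump
kernel scaled by the group's event amplitude is added to every ROI of a
randomly chosen community.  The smooth noise floor keeps the RSS trace from
producing spurious local minima, so troughs fall between events and the
trough-to-trough duration tracks the inter-event interval: a group with a
lower event rate shows longer TTD, and one with a lower event amplitude
shows lower RSS peak amplitude.

Site effects are applied to the raw signal as a per-ROI additive shift and
multiplicative scale drawn once per site, so downstream harmonization has a
real batch effect to remove.  Everything is driven by one master seed
through spawned generators, making cohorts byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ets import RoiTimeSeries

METADATA_COLUMNS = ("subject_id", "group", "site", "apoe4_count", "mmse", "moca")


class SpecValidationError(ValueError):
    """A CohortSpec field failed validation; the message names the field."""


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    n_per_group: int = 20
    n_roi: int = 40
    n_frames: int = 200
    tr_seconds: float = 3.0
    n_communities: int = 4
    event_rate_per_group: tuple = (0.20, 0.12)
    event_amplitude_per_group: tuple = (3.0, 2.0)
    noise_sd: float = 1.0
    n_sites: int = 2
    site_shift_sd: float = 0.0
    site_scale_sd: float = 0.0
    seed: int = 0
    group_labels: tuple = ("HC", "SCD")
    noise_smooth_sd: float = 2.0
    event_kernel: tuple = (0.3, 0.7, 1.0, 0.7, 0.3)
    fixed_interval: bool = False
    apoe_probs: tuple = (0.60, 0.33, 0.07)
    mmse_mean: float = 29.1
    mmse_sd: float = 1.1
    moca_mean: float = 26.3
    moca_sd: float = 2.2
    mmse_amplitude_slope: float = 0.0

    def validate(self) -> None:
        for field in ("n_per_group", "n_roi", "n_frames", "n_communities", "n_sites"):
            if int(getattr(self, field)) < 1:
                raise SpecValidationError(f"{field} must be >= 1")
        if self.n_frames < 20:
            raise SpecValidationError("n_frames must be >= 20")
        if self.n_roi < self.n_communities:
            raise SpecValidationError("n_roi must be >= n_communities")
        if not (self.tr_seconds > 0):
            raise SpecValidationError("tr_seconds must be positive")
        if len(self.event_rate_per_group) != 2 or len(self.event_amplitude_per_group) != 2:
            raise SpecValidationError(
                "event_rate_per_group and event_amplitude_per_group need one value per group"
            )
        for r in self.event_rate_per_group:
            if not (0 < r < 1):
                raise SpecValidationError("event_rate_per_group values must lie in (0, 1)")
        for a in self.event_amplitude_per_group:
            if a < 0:
                raise SpecValidationError("event_amplitude_per_group values must be >= 0")
        for field in ("noise_sd", "site_shift_sd", "site_scale_sd"):
            if getattr(self, field) < 0:
                raise SpecValidationError(f"{field} must be >= 0")
        if self.noise_smooth_sd < 0:
            raise SpecValidationError("noise_smooth_sd must be >= 0")
        if len(self.group_labels) != 2:
            raise SpecValidationError("group_labels needs exactly 2 labels")
        if abs(sum(self.apoe_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.apoe_probs):
            raise SpecValidationError("apoe_probs must be nonnegative and sum to 1")

    def communities(self) -> list:
        """Disjoint, near-equal ROI index blocks; loadings 1 inside, 0 outside."""
        return [np.asarray(b) for b in np.array_split(np.arange(self.n_roi), self.n_communities)]


@dataclasses.dataclass(frozen=True)
class SubjectTruth:
    event_frames: np.ndarray
    event_communities: np.ndarray
    event_amplitude: float
    group: str
    site: int


@dataclasses.dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    series: list  # of RoiTimeSeries
    metadata: pd.DataFrame
    truth: list  # of SubjectTruth


def _smooth_noise(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Temporally smooth Gaussian noise, marginal SD = noise_sd, ROI x T.

    White innovations convolved with a unit-energy Gaussian kernel
    (``noise_smooth_sd`` frames wide); smoothness mimics band-passed BOLD
    and keeps the RSS trace from sprouting local minima at the frame scale,
    so trough spacing is governed by the event process.
    """
    if spec.noise_smooth_sd == 0:
        return rng.normal(0.0, spec.noise_sd, size=(spec.n_roi, spec.n_frames))
    half = int(np.ceil(4 * spec.noise_smooth_sd))
    taps = np.exp(-0.5 * (np.arange(-half, half + 1) / spec.noise_smooth_sd) ** 2)
    taps /= np.linalg.norm(taps)  # unit L2 norm preserves the marginal SD
    innov = rng.normal(0.0, spec.noise_sd, size=(spec.n_roi, spec.n_frames + 2 * half))
    out = np.empty((spec.n_roi, spec.n_frames))
    for r in range(spec.n_roi):
        out[r] = np.convolve(innov[r], taps, mode="valid")
    return out


def _draw_event_frames(spec: CohortSpec, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Renewal process: geometric inter-event intervals with mean 1/rate."""
    frames = []
    if spec.fixed_interval:
        step = max(int(round(1 / rate)), 1)
        t = step - 1
        while t < spec.n_frames:
            frames.append(t)
            t += step
    else:
        t = int(rng.geometric(rate)) - 1
        while t < spec.n_frames:
            frames.append(t)
            t += int(rng.geometric(rate))
    return np.asarray(frames, dtype=int)


def generate_subject(
    spec: CohortSpec,
    group_index: int,
    site_index: int,
    rng: np.random.Generator,
    subject_id: str = "sub",
    site_shift: np.ndarray | None = None,
    site_scale: np.ndarray | None = None,
) -> tuple[RoiTimeSeries, SubjectTruth]:
    """One subject's ROI x T matrix plus ground-truth event record."""
    spec.validate()
    rate = float(spec.event_rate_per_group[group_index])
    amplitude = float(spec.event_amplitude_per_group[group_index])
    data = _smooth_noise(spec, rng)
    frames = _draw_event_frames(spec, rate, rng)
    comms = spec.communities()
    which = rng.integers(0, spec.n_communities, size=frames.size)
    kernel = np.asarray(spec.event_kernel, dtype=float)
    half = len(kernel) // 2
    for t, c in zip(frames, which):
        members = comms[int(c)]
        lo = max(t - half, 0)
        hi = min(t - half + len(kernel), spec.n_frames)
        seg = kernel[lo - (t - half) : hi - (t - half)]
        data[np.ix_(members, np.arange(lo, hi))] += amplitude * seg
    if site_shift is not None:
        data = data * site_scale[:, None] + site_shift[:, None]
    labels = tuple(f"roi{r:03d}" for r in range(spec.n_roi))
    series = RoiTimeSeries(
        subject_id=subject_id, data=data, roi_labels=labels, tr_seconds=spec.tr_seconds
    )
    truth = SubjectTruth(
        event_frames=frames,
        event_communities=which,
        event_amplitude=amplitude,
        group=str(spec.group_labels[group_index]),
        site=int(site_index),
    )
    return series, truth


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Balanced two-group cohort; subjects assigned round-robin to sites.

    Metadata carries simulated APOE e4 allele counts (multinomial over
    ``apoe_probs``), and MMSE/MoCA scores sampled from Gaussians (MMSE
    optionally tied to the subject's event amplitude through
    ``mmse_amplitude_slope``), truncated to [0, 30].
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    site_rng, meta_rng, *subj_seeds = ss.spawn(2 + 2 * spec.n_per_group)
    site_rng = np.random.default_rng(site_rng)
    meta_rng = np.random.default_rng(meta_rng)

    site_shift = site_rng.normal(0.0, spec.site_shift_sd, size=(spec.n_sites, spec.n_roi))
    site_scale = np.exp(site_rng.normal(0.0, spec.site_scale_sd, size=(spec.n_sites, spec.n_roi)))

    series: list = []
    truths: list = []
    rows: list = []
    idx = 0
    for g in range(2):
        for k in range(spec.n_per_group):
            site = idx % spec.n_sites
            sid = f"sub{idx:04d}"
            rng = np.random.default_rng(subj_seeds[idx])
            s, truth = generate_subject(
                spec,
                group_index=g,
                site_index=site,
                rng=rng,
                subject_id=sid,
                site_shift=site_shift[site],
                site_scale=site_scale[site],
            )
            apoe = int(meta_rng.choice(3, p=np.asarray(spec.apoe_probs)))
            mmse = (
                spec.mmse_mean
                + spec.mmse_amplitude_slope * truth.event_amplitude
                + meta_rng.normal(0.0, spec.mmse_sd)
            )
            moca = spec.moca_mean + meta_rng.normal(0.0, spec.moca_sd)
            rows.append(
                {
                    "subject_id": sid,
                    "group": truth.group,
                    "site": site,
                    "apoe4_count": apoe,
                    "mmse": float(np.clip(mmse, 0.0, 30.0)),
                    "moca": float(np.clip(moca, 0.0, 30.0)),
                }
            )
            series.append(s)
            truths.append(truth)
            idx += 1
    metadata = pd.DataFrame(rows, columns=list(METADATA_COLUMNS))
    return SyntheticCohort(spec=spec, series=series, metadata=metadata, truth=truths)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write one delimited-text matrix per subject (rows = frames) + metadata CSV."""
    from .io import write_roi_series

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.series:
        write_roi_series(s, out / f"{s.subject_id}.csv")
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    with open(out / "cohort_spec.json", "w") as fh:
        json.dump(dataclasses.asdict(cohort.spec), fh, indent=2, default=list)


def spec_from_json(path) -> CohortSpec:
    with open(path) as fh:
        raw = json.load(fh)
    tuple_fields = {
        "event_rate_per_group",
        "event_amplitude_per_group",
        "group_labels",
        "event_kernel",
        "apoe_probs",
    }
    kwargs = {k: (tuple(v) if k in tuple_fields else v) for k, v in raw.items()}
    spec = CohortSpec(**kwargs)
    spec.validate()
    return spec
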
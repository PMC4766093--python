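"""Synthetic DCE cohort generator.

Emulates the study design end to end so the whole pipeline is testable
without patient data: a cohort (default 14 subjects) imaged before
ablation, within 48 h after, and at weeks 2/4/6/10, with weekly serum
sampling through week 6 plus week 10.  Each subject gets

* a ground-truth K^trans trajectory — baseline 0.22 1/min (the cohort's
  pre-treatment mean) jumping to its maximum at the first post-ablation
  visit and decaying back toward baseline by ~4 weeks;
* a serum BSE trajectory — a smooth bump over baseline peaking between
  days 7 and 21 and back within 10 % of baseline by day 42, optionally
  preceded by a small immediate post-ablation dip (half the cohort);
* a FLAIR-area trajectory peaking near day 14;
* a digital phantom per visit: an ablation-cavity ellipsoid, an
  enhancing rim shell within 1 cm of the cavity margin carrying the
  SPGR signal of the Tofts tissue curve, one arterial voxel carrying
  the blood signal of the population AIF, and i.i.d. Gaussian noise.

Inter-subject heterogeneity is log-normal multiplicative jitter on
amplitudes and timescales, clipped so every truth stays strictly inside
the fitting priors and every trajectory invariant holds by
construction.  Seeding is hierarchical (master seed + subject index +
visit index via ``numpy.random.SeedSequence``), so adding a subject
does not reshuffle the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .curves import ConcentrationCurve, SECONDS_PER_MINUTE
from .pk_models import ToftsParams, tofts_forward
from .roi_pipeline import ROIMask
from .signal_model import AcquisitionProtocol, spgr_signal

__all__ = [
    "AIFParams",
    "CohortConfig",
    "PhantomSpec",
    "SubjectGroundTruth",
    "population_aif",
    "ktrans_trajectory",
    "bse_trajectory",
    "flair_trajectory",
    "generate_visit_image",
    "generate_cohort",
]


class AIFParams(BaseModel):
    """Generative population arterial input function (plasma, mM, minutes).

    A gamma-variate first-pass bolus peaking ``peak_delay`` after
    arrival, plus a smaller recirculation/washout term that rises with a
    short time constant and decays bi-exponentially.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    arrival: float = 0.6  # min, after the pre-contrast baseline window
    peak_delay: float = 0.25  # min from arrival to bolus peak
    sharpness: float = 3.0  # gamma shape
    peak_amplitude: float = 6.0  # mM plasma at the bolus peak
    washout_amplitude: float = 1.0  # mM plateau scale
    washout_rise: float = 0.3  # min
    washout_fast_rate: float = 0.15  # 1/min
    washout_slow_rate: float = 0.01  # 1/min
    washout_fast_fraction: float = 0.7


def population_aif(
    times_min: np.ndarray, params: Optional[AIFParams] = None
) -> ConcentrationCurve:
    """Evaluate the population AIF on a time grid (minutes)."""
    p = params or AIFParams()
    t = np.asarray(times_min, dtype=float)
    u = t - p.arrival
    pos = u > 0
    vals = np.zeros_like(t)
    uu = np.where(pos, u, 1.0)
    bolus = p.peak_amplitude * (uu / p.peak_delay) ** p.sharpness * np.exp(
        p.sharpness * (1.0 - uu / p.peak_delay)
    )
    washout = (
        p.washout_amplitude
        * (1.0 - np.exp(-uu / p.washout_rise))
        * (
            p.washout_fast_fraction * np.exp(-p.washout_fast_rate * uu)
            + (1.0 - p.washout_fast_fraction) * np.exp(-p.washout_slow_rate * uu)
        )
    )
    vals[pos] = (bolus + washout)[pos]
    return ConcentrationCurve(t, vals)


# ---------------------------------------------------------------------------
# ground-truth longitudinal trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KtransTrajectoryParams:
    """Baseline + post-ablation exponential washout of the excess."""

    baseline: float = 0.22  # 1/min, cohort pre-treatment mean
    amplitude: float = 0.5  # 1/min excess at the first post-ablation visit
    decay_days: float = 10.0  # e-folding of the excess
    onset_day: int = 1  # first post-ablation visit


@dataclass(frozen=True)
class BumpTrajectoryParams:
    """Log-normal bump over baseline for serum BSE / FLAIR area.

    value(d) = baseline + amplitude · exp(−ln²(d/peak_day)/(2·width²))
    for d > 0, plus an optional small immediate post-ablation dip.
    """

    baseline: float
    amplitude: float
    peak_day: float
    width: float
    dip_fraction: float = 0.0  # fraction of baseline dipped right after ablation


def ktrans_trajectory(
    params: KtransTrajectoryParams, visit_days: Sequence[int]
) -> np.ndarray:
    """True K^trans at each visit day (pre-ablation days at baseline)."""
    days = np.asarray(visit_days, dtype=float)
    excess = np.where(
        days >= params.onset_day,
        params.amplitude * np.exp(-(days - params.onset_day) / params.decay_days),
        0.0,
    )
    return params.baseline + excess


def _bump(params: BumpTrajectoryParams, days: np.ndarray) -> np.ndarray:
    days = np.asarray(days, dtype=float)
    out = np.full(days.shape, params.baseline)
    post = days > 0
    d = np.where(post, days, 1.0)
    bump = params.amplitude * np.exp(
        -np.log(d / params.peak_day) ** 2 / (2.0 * params.width**2)
    )
    dip = (
        params.dip_fraction
        * params.baseline
        * np.exp(-((d - 1.0) / 2.0) ** 2)
    )
    out[post] = (params.baseline + bump - dip)[post]
    return out


def bse_trajectory(
    params: BumpTrajectoryParams, serum_days: Sequence[int]
) -> np.ndarray:
    """True serum BSE (ng/mL) on the serum sampling schedule."""
    return _bump(params, np.asarray(serum_days))


def flair_trajectory(
    params: BumpTrajectoryParams, days: Sequence[int]
) -> np.ndarray:
    """True FLAIR maximal-slice area (mm²) on the imaging schedule."""
    return _bump(params, np.asarray(days))


def _max_bump_width(
    amplitude: float, baseline: float, peak_day: float,
    horizon_day: float = 42.0, return_fraction: float = 0.08,
) -> float:
    """Largest width for which the bump at ``horizon_day`` has decayed to
    ``return_fraction`` of baseline (guarantees the return-to-baseline
    invariant for any sampled peak day)."""
    excess = np.log(amplitude / (return_fraction * baseline))
    if excess <= 0:
        return np.inf
    return abs(np.log(horizon_day / peak_day)) / np.sqrt(2.0 * excess)


# ---------------------------------------------------------------------------
# cohort configuration and subject truths
# ---------------------------------------------------------------------------


class PhantomSpec(BaseModel):
    """Geometry of the digital visit phantom (desk-scale grid)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    grid_shape: Tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: Tuple[float, float, float] = (1.5, 1.5, 4.0)
    cavity_center: Tuple[float, float, float] = (16.0, 16.0, 8.0)  # voxels
    cavity_semiaxes_mm: Tuple[float, float, float] = (9.0, 9.0, 8.0)
    rim_thickness_mm: float = 6.0  # shell within 1 cm of the cavity margin
    vessel_voxel: Tuple[int, int, int] = (4, 4, 8)
    m0: float = 1000.0  # scanner-unit proton density scale

    def masks(self) -> Tuple[np.ndarray, np.ndarray]:
        """(cavity_mask, rim_mask) on the voxel grid."""
        if self.rim_thickness_mm > 10.0:
            raise ValueError("rim shell must stay within 1 cm of the margin")
        idx = np.indices(self.grid_shape, dtype=float)
        off = [
            (idx[i] - self.cavity_center[i]) * self.voxel_size_mm[i]
            for i in range(3)
        ]
        rho = np.sqrt(sum((off[i] / self.cavity_semiaxes_mm[i]) ** 2 for i in range(3)))
        cavity = rho <= 1.0
        mean_ax = float(np.mean(self.cavity_semiaxes_mm))
        rim = (rho > 1.0) & ((rho - 1.0) * mean_ax <= self.rim_thickness_mm)
        rim[self.vessel_voxel] = False  # rim and vessel are disjoint
        return cavity, rim


class CohortConfig(BaseModel):
    """Study-design parameters of the synthetic cohort."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_subjects: int = 14
    visit_days: Tuple[int, ...] = (-1, 1, 14, 28, 42, 70)
    serum_days: Tuple[int, ...] = (-1, 1, 7, 14, 21, 28, 35, 42, 70)
    protocol: AcquisitionProtocol = AcquisitionProtocol()
    phantom: PhantomSpec = PhantomSpec()
    aif: AIFParams = AIFParams()
    noise_level: float = 0.02  # image noise sd as fraction of peak rim signal
    serum_cv: float = 0.05  # serum assay coefficient of variation
    flair_cv: float = 0.03
    dip_probability: float = 0.5  # fraction with an immediate post-LITT BSE dip
    seed: int = 0
    compress_images: bool = True

    def model_post_init(self, __context) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if list(self.visit_days) != sorted(self.visit_days):
            raise ValueError("visit days must be sorted")
        if self.visit_days[0] >= 0 or sum(d > 0 for d in self.visit_days) < 2:
            raise ValueError("need one pre-ablation visit and >= 2 post visits")


@dataclass(frozen=True)
class SubjectGroundTruth:
    """Per-subject generating parameters (all inside the fitting priors)."""

    subject: str
    ktrans: KtransTrajectoryParams
    ve: float
    bse: BumpTrajectoryParams
    flair: BumpTrajectoryParams


def _draw_subject_truth(subject: str, rng: np.random.Generator,
                        dip: bool) -> SubjectGroundTruth:
    """Sample one subject's trajectory parameters with log-normal jitter,
    clipped so every invariant holds for every draw."""
    kt = KtransTrajectoryParams(
        baseline=float(np.clip(0.22 * rng.lognormal(0.0, 0.2), 0.08, 0.6)),
        amplitude=float(np.clip(0.5 * rng.lognormal(0.0, 0.3), 0.15, 1.5)),
        decay_days=float(np.clip(10.0 * rng.lognormal(0.0, 0.15), 6.0, 11.0)),
    )
    ve = float(np.clip(0.3 * rng.lognormal(0.0, 0.15), 0.08, 0.7))

    bse_baseline = float(np.clip(8.0 * rng.lognormal(0.0, 0.2), 4.0, 16.0))
    bse_amp = float(np.clip(12.0 * rng.lognormal(0.0, 0.3), 5.0, 30.0))
    bse_peak = float(np.clip(14.0 * rng.lognormal(0.0, 0.15), 7.5, 20.0))
    w_cap = _max_bump_width(bse_amp, bse_baseline, bse_peak)
    bse_width = float(min(0.35 * rng.lognormal(0.0, 0.1), w_cap))
    bse = BumpTrajectoryParams(
        baseline=bse_baseline, amplitude=bse_amp, peak_day=bse_peak,
        width=bse_width, dip_fraction=0.08 if dip else 0.0,
    )

    flair = BumpTrajectoryParams(
        baseline=float(np.clip(500.0 * rng.lognormal(0.0, 0.25), 200.0, 1200.0)),
        amplitude=float(np.clip(800.0 * rng.lognormal(0.0, 0.3), 300.0, 2000.0)),
        peak_day=float(np.clip(14.0 * rng.lognormal(0.0, 0.1), 10.0, 18.0)),
        width=0.5,
    )
    return SubjectGroundTruth(subject=subject, ktrans=kt, ve=ve, bse=bse, flair=flair)


# ---------------------------------------------------------------------------
# phantom image synthesis
# ---------------------------------------------------------------------------


def generate_visit_image(
    truth: ToftsParams,
    phantom: PhantomSpec,
    protocol: AcquisitionProtocol,
    aif_params: Optional[AIFParams] = None,
    noise_level: float = 0.02,
    seed: int = 0,
) -> Tuple[np.ndarray, ROIMask, Tuple[int, int, int]]:
    """Synthesize one 4D dynamic visit.

    The rim shell carries the SPGR signal of the Tofts tissue curve
    driven by the population plasma AIF; the vessel voxel carries the
    SPGR signal of the whole-blood AIF; everything else sits at the
    pre-contrast tissue baseline.  Gaussian noise with sd
    ``noise_level`` × (peak rim signal) is added i.i.d. to every voxel
    and frame.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    times_min = protocol.frame_times() / SECONDS_PER_MINUTE
    plasma = population_aif(times_min, aif_params)
    blood_conc = plasma.values * (1.0 - protocol.hematocrit)
    tissue = tofts_forward(truth, plasma)

    m0 = phantom.m0
    rim_signal = spgr_signal(tissue.values, protocol, m0=m0)
    vessel_signal = spgr_signal(blood_conc, protocol, m0=m0, t10=protocol.t10_blood)
    bg_signal = float(spgr_signal(0.0, protocol, m0=m0))
    cavity_signal = float(spgr_signal(0.0, protocol, m0=0.6 * m0))

    cavity, rim = phantom.masks()
    nframes = len(times_min)
    img = np.full(phantom.grid_shape + (nframes,), bg_signal, dtype=np.float32)
    img[cavity, :] = cavity_signal
    img[rim, :] = rim_signal.astype(np.float32)
    img[phantom.vessel_voxel] = vessel_signal.astype(np.float32)

    if noise_level > 0:
        sd = noise_level * float(rim_signal.max())
        img = img + rng.normal(0.0, sd, size=img.shape).astype(np.float32)
        np.maximum(img, 0.0, out=img)

    mask = ROIMask(rim, phantom.voxel_size_mm)
    return img, mask, phantom.vessel_voxel


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master_seed, subject_index)))


def _visit_seed(master_seed: int, subject_index: int, visit_index: int) -> int:
    ss = np.random.SeedSequence((master_seed, subject_index, visit_index))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _affine(voxel_size_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> Dict[str, Path]:
    """Write a full synthetic cohort to ``out_dir``.

    Emits per-visit dynamic NIfTI images, one rim-ROI mask per subject
    (grids are co-registered across visits), a visit manifest CSV, a
    tidy longitudinal CSV of noisy serum BSE and FLAIR measurements,
    and a ground-truth table for recovery scoring.  Returns the paths.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    proto = config.protocol
    suffix = ".nii.gz" if config.compress_images else ".nii"
    affine = _affine(config.phantom.voxel_size_mm)

    manifest_rows = []
    tidy_rows = []
    truth_rows = []

    for si in range(config.n_subjects):
        subject = f"S{si + 1:02d}"
        rng = _subject_rng(config.seed, si)
        dip = bool(rng.random() < config.dip_probability)
        truth = _draw_subject_truth(subject, rng, dip)

        kt_true = ktrans_trajectory(truth.ktrans, config.visit_days)
        bse_true = bse_trajectory(truth.bse, config.serum_days)
        flair_true = flair_trajectory(truth.flair, config.visit_days)

        mask_path = out / "images" / f"{subject}_rim_mask{suffix}"
        mask_written = False

        for vi, day in enumerate(config.visit_days):
            params = ToftsParams(ktrans=float(kt_true[vi]), ve=truth.ve)
            img, mask, vessel = generate_visit_image(
                params,
                config.phantom,
                proto,
                aif_params=config.aif,
                noise_level=config.noise_level,
                seed=_visit_seed(config.seed, si, vi),
            )
            if not mask_written:
                nib.save(
                    nib.Nifti1Image(mask.data.astype(np.uint8), affine),
                    str(mask_path),
                )
                mask_written = True
            img_path = out / "images" / f"{subject}_day{day:+04d}{suffix}"
            nib.save(nib.Nifti1Image(img, affine), str(img_path))
            manifest_rows.append(
                {
                    "subject": subject,
                    "day": day,
                    "image_path": str(img_path),
                    "mask_path": str(mask_path),
                    "aif_i": vessel[0],
                    "aif_j": vessel[1],
                    "aif_k": vessel[2],
                }
            )
            truth_rows.append(
                {
                    "subject": subject,
                    "day": day,
                    "ktrans_true": float(kt_true[vi]),
                    "ve_true": truth.ve,
                    "flair_true": float(flair_true[vi]),
                    "bse_baseline": truth.bse.baseline,
                    "bse_peak_day": truth.bse.peak_day,
                    "bse_amplitude": truth.bse.amplitude,
                    "bse_width": truth.bse.width,
                    "bse_dip_fraction": truth.bse.dip_fraction,
                    "ktrans_baseline": truth.ktrans.baseline,
                    "flair_peak_day": truth.flair.peak_day,
                }
            )
            flair_noisy = float(
                flair_true[vi] * (1.0 + config.flair_cv * rng.standard_normal())
            )
            tidy_rows.append(
                {"subject": subject, "day": day, "modality": "flair",
                 "value": max(flair_noisy, 0.0)}
            )
        for di, day in enumerate(config.serum_days):
            bse_noisy = float(
                bse_true[di] * (1.0 + config.serum_cv * rng.standard_normal())
            )
            tidy_rows.append(
                {"subject": subject, "day": day, "modality": "bse",
                 "value": max(bse_noisy, 0.0)}
            )

    paths = {
        "manifest": out / "manifest.csv",
        "longitudinal": out / "longitudinal.csv",
        "truth": out / "truth.csv",
        "config": out / "cohort_config.json",
    }
    pd.DataFrame(manifest_rows).to_csv(paths["manifest"], index=False)
    pd.DataFrame(tidy_rows).to_csv(paths["longitudinal"], index=False)
    pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    paths["config"].write_text(config.model_dump_json(indent=2))
    return paths
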
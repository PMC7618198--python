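"""Evaluation metrics: normalized RMSE and time-series stability (tSNR)."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = ["nrmse", "tsnr", "TimeSeriesReport"]


def nrmse(test: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized root-mean-square error ||test - ref|| / ||ref||.

    Computed over magnitudes inside the mask (everywhere if omitted).
    """
    test = np.abs(np.asarray(test))
    reference = np.abs(np.asarray(reference))
    if test.shape != reference.shape:
        raise ValueError("shapes differ")
    if mask is None:
        mask = np.ones(test.shape, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    ref_norm = np.linalg.norm(reference[mask])
    if ref_norm == 0:
        raise ValueError("zero-norm reference")
    return float(np.linalg.norm((test - reference)[mask]) / ref_norm)


@dataclass
class TimeSeriesReport:
    """Temporal-stability summary of an image time series.

    tSNR is the voxelwise temporal mean over temporal standard deviation
    (sample SD, n-1 denominator), computed over non-excluded volumes.
    Voxels with zero temporal SD carry an infinite tSNR and are reported
    through the clipped ``tsnr_map`` (clipped at ``tsnr_clip``).
    """

    sd_map: np.ndarray
    tsnr_map: np.ndarray
    mean_map: np.ndarray
    mask: np.ndarray
    excluded: list[int]
    mean_sd: float
    mean_tsnr: float
    tsnr_clip: float
    motion_params: list | None = None
    extras: dict = dc_field(default_factory=dict)


def tsnr(
    series: np.ndarray,
    excluded: list[int] | None = None,
    mask: np.ndarray | None = None,
    tsnr_clip: float = 1e6,
    motion_params: list | None = None,
) -> TimeSeriesReport:
    """Temporal SD and tSNR maps of a (n_volumes, n1, n2) series.

    ``excluded`` volumes (e.g. motion-corrupted ones) are dropped before
    any statistic is computed; at least 3 volumes must remain.
    """
    series = np.abs(np.asarray(series))
    excluded = sorted(set(excluded or []))
    keep = [v for v in range(series.shape[0]) if v not in excluded]
    if len(keep) < 3:
        raise ValueError("need at least 3 non-excluded volumes")
    sub = series[keep]
    mean_map = sub.mean(axis=0)
    sd_map = sub.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd_map > 0, mean_map / np.where(sd_map > 0, sd_map, 1.0), np.inf)
    t = np.clip(t, None, tsnr_clip)
    if mask is None:
        mask = np.ones(mean_map.shape, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    return TimeSeriesReport(
        sd_map=sd_map,
        tsnr_map=t,
        mean_map=mean_map,
        mask=mask,
        excluded=excluded,
        mean_sd=float(sd_map[mask].mean()),
        mean_tsnr=float(t[mask].mean()),
        tsnr_clip=tsnr_clip,
        motion_params=motion_params,
    )


def tsnr_ratio(report_a: TimeSeriesReport, report_b: TimeSeriesReport) -> float:
    """Masked mean of the voxelwise tSNR ratio a/b (ratio first, then mean)."""
    mask = report_a.mask & report_b.mask & (report_b.tsnr_map > 0)
    return float((report_a.tsnr_map[mask] / report_b.tsnr_map[mask]).mean())
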
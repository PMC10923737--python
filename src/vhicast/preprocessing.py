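"""Temporal compositing and gap filling.

Daily NDVI is aligned to the MODIS 8-day compositing calendar (periods start
on day-of-year 1, 9, ..., 361 and restart every January 1, so the final
period of each year is truncated to 5 days, 6 in leap years; 46 periods per
year, 460 over 2012-2021). Missing cells are then filled by 1-D linear
interpolation, either along image rows (spatial mode, the default) or along
each pixel's time series (temporal mode).
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np

from .core_io import (
    MODIS_DOY_STARTS,
    RasterCube,
    StepKind,
    TimeAxis,
    ValidationError,
)

__all__ = ["CompositeCalendar", "build_calendar", "compose_8day", "fill_gaps"]


@dataclasses.dataclass(frozen=True)
class CompositeCalendar:
    """Ordered, non-overlapping (start, end-exclusive) composite periods."""

    periods: tuple[tuple[dt.date, dt.date], ...]

    def __post_init__(self) -> None:
        for start, end in self.periods:
            if start.timetuple().tm_yday not in MODIS_DOY_STARTS:
                raise ValidationError(f"period start {start} not on the MODIS day-of-year grid")
            if not end > start:
                raise ValidationError(f"empty period {start}..{end}")
        for (_, e), (s, _) in zip(self.periods, self.periods[1:]):
            if s != e:
                raise ValidationError(f"periods do not tile: gap/overlap at {e} vs {s}")

    def __len__(self) -> int:
        return len(self.periods)

    def starts(self) -> tuple[dt.date, ...]:
        return tuple(s for s, _ in self.periods)


def build_calendar(start_date: dt.date, end_date: dt.date) -> CompositeCalendar:
    """All MODIS composite periods whose start lies in [start_date, end_date)."""
    if start_date >= end_date:
        raise ValidationError("start_date must precede end_date")
    periods: list[tuple[dt.date, dt.date]] = []
    for year in range(start_date.year, end_date.year + 1):
        jan1 = dt.date(year, 1, 1)
        for i, doy in enumerate(MODIS_DOY_STARTS):
            p_start = jan1 + dt.timedelta(days=doy - 1)
            if doy == MODIS_DOY_STARTS[-1]:
                p_end = dt.date(year + 1, 1, 1)  # truncated final period of the year
            else:
                p_end = p_start + dt.timedelta(days=8)
            if start_date <= p_start < end_date:
                periods.append((p_start, p_end))
    if not periods:
        raise ValidationError("no composite period starts inside the requested range")
    return CompositeCalendar(tuple(periods))


def compose_8day(daily: RasterCube, calendar: CompositeCalendar) -> RasterCube:
    """Per-pixel mean of unmasked daily values within each composite period.

    A pixel with no unmasked daily value in a period is masked in the output.
    """
    if daily.time.step_kind is not StepKind.daily:
        raise ValidationError("compose_8day expects a daily cube")
    dates = np.array([d.toordinal() for d in daily.time.timestamps])
    T_out = len(calendar)
    H, W = daily.grid_shape
    values = np.zeros((T_out, H, W), dtype=np.float64)
    mask = np.ones((T_out, H, W), dtype=bool)
    any_overlap = False
    valid = (~daily.mask).astype(np.float64)
    data = np.where(daily.mask, 0.0, daily.values.astype(np.float64))
    for i, (start, end) in enumerate(calendar.periods):
        sel = (dates >= start.toordinal()) & (dates < end.toordinal())
        if not sel.any():
            continue
        any_overlap = True
        counts = valid[sel].sum(axis=0)
        sums = data[sel].sum(axis=0)
        has = counts > 0
        values[i][has] = sums[has] / counts[has]
        mask[i] = ~has
    if not any_overlap:
        raise ValidationError("daily cube does not overlap any calendar period")
    return RasterCube(
        variable=daily.variable,
        values=values.astype(np.float32),
        mask=mask,
        time=TimeAxis(calendar.starts(), StepKind.composite_8day),
        units=daily.units,
        attrs=dict(daily.attrs),
    )


def _interp_line(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linearly interpolate masked entries of a 1-D line.

    Interior gaps are interpolated between the nearest unmasked neighbours;
    gaps touching an edge are filled by nearest-neighbour extension.
    Unmasked entries are returned untouched (bitwise).
    """
    out = values.copy()
    if not mask.any():
        return out
    known = np.flatnonzero(~mask)
    missing = np.flatnonzero(mask)
    out[missing] = np.interp(missing, known, values[known])
    return out


def fill_gaps(cube: RasterCube, mode: str = "spatial") -> RasterCube:
    """Fill masked cells by 1-D linear interpolation; output mask is all-false.

    spatial mode: each row of each frame is scanned left-to-right; cells in
    rows with no observation fall back to column-wise interpolation, then to
    the frame mean. temporal mode: the same rule along each pixel's series.
    """
    out = cube.copy()
    T, H, W = cube.shape
    if mode == "temporal":
        empty = cube.mask.all(axis=0)
        if empty.any():
            r, c = np.argwhere(empty)[0]
            raise ValidationError(f"pixel ({r}, {c}) has no observations in any frame")
        for r in range(H):
            for c in range(W):
                m = cube.mask[:, r, c]
                if m.any():
                    out.values[:, r, c] = _interp_line(cube.values[:, r, c], m)
    elif mode == "spatial":
        empty_frames = cube.mask.all(axis=(1, 2))
        if empty_frames.any():
            raise ValidationError(f"frame {int(np.argmax(empty_frames))} is entirely masked")
        for t in range(T):
            fmask = cube.mask[t]
            if not fmask.any():
                continue
            frame = out.values[t]
            row_has_obs = ~fmask.all(axis=1)
            for r in range(H):
                if row_has_obs[r] and fmask[r].any():
                    frame[r] = _interp_line(frame[r], fmask[r])
            remaining = fmask & ~row_has_obs[:, None]
            if remaining.any():
                col_has_obs = ~fmask.all(axis=0)
                for c in range(W):
                    col_missing = remaining[:, c]
                    if not col_missing.any():
                        continue
                    if col_has_obs[c]:
                        known = np.flatnonzero(~fmask[:, c])
                        frame[col_missing, c] = np.interp(
                            np.flatnonzero(col_missing), known, frame[known, c]
                        )
                    else:
                        frame[col_missing, c] = frame[~fmask].mean()
    else:
        raise ValidationError(f"unknown fill mode {mode!r}")
    out.mask = np.zeros_like(cube.mask)
    return out
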
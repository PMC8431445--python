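"""Image processing for MELC stacks.

Four corrections, applied in order:

1. rigid registration of every cycle against a reference cycle, estimated on
   the phase-contrast images and applied to all three images of the cycle;
2. flat-field correction with brightfield/darkframe calibration images,
   removing the fixed illumination pattern;
3. subtraction of the previous cycle's post-bleach image from the current
   fluorescence tag image, removing accumulated residual bleaching signal;
4. vignetting correction with a multiplicative gain field estimated from the
   whole stack of tag images (robust per-pixel statistic + heavy smoothing),
   or with a precomputed gain map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation


@dataclass
class CalibrationImages:
    """Brightfield and darkframe calibration acquisitions."""

    brightfield: np.ndarray
    darkframe: np.ndarray

    def __post_init__(self) -> None:
        self.brightfield = np.asarray(self.brightfield, dtype=np.float64)
        self.darkframe = np.asarray(self.darkframe, dtype=np.float64)
        if self.brightfield.shape != self.darkframe.shape:
            raise ValueError("brightfield and darkframe shapes differ")


@dataclass
class MelcCycle:
    """One staining cycle: fluorescence tag, post-bleach and phase image."""

    index: int  # 1-based position in the imaging sequence
    marker: str
    tag_image: np.ndarray
    postbleach_image: np.ndarray
    phase_image: np.ndarray
    is_negative_control: bool = False
    nc_partner: str | None = None

    def __post_init__(self) -> None:
        shapes = {self.tag_image.shape, self.postbleach_image.shape, self.phase_image.shape}
        if len(shapes) != 1:
            raise ValueError("tag/post-bleach/phase images of a cycle must share a shape")


@dataclass
class MelcRun:
    """An ordered cyclic acquisition plus its calibration images."""

    cycles: list[MelcCycle]
    calibration: CalibrationImages | None = None
    pixel_size_um: float = 0.45
    sample_id: str = "sample"
    fov_id: str = "fov1"

    def __post_init__(self) -> None:
        if len(self.cycles) < 1:
            raise ValueError("a run needs at least one cycle")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.cycles[0].tag_image.shape

    @property
    def fov_size_um(self) -> float:
        return self.image_shape[0] * self.pixel_size_um

    def cycle_for(self, marker: str) -> MelcCycle:
        for c in self.cycles:
            if c.marker == marker:
                return c
        raise KeyError(f"marker {marker!r} not in run")


@dataclass
class GainField:
    """Multiplicative shading field, strictly positive, mean-normalized to 1."""

    gain: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=np.float64)
        if np.any(g <= 0):
            raise ValueError("gain field must be strictly positive")
        if abs(g.mean() - 1.0) > 1e-9:
            raise ValueError("gain field must be mean-normalized to 1")
        self.gain = g


class RegistrationError(RuntimeError):
    pass


def _apply_shift(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Translate an image, filling exposed pixels with 0."""
    return ndimage.shift(np.asarray(image, dtype=np.float64), shift, order=0, cval=0.0)


def register_run(
    run: MelcRun,
    reference_cycle: int = 1,
    max_shift: float = 50.0,
    on_failure: str = "error",
    upsample_factor: int = 1,
) -> tuple[MelcRun, "list[dict]"]:
    """Rigidly align every cycle to a reference cycle.

    One translation per cycle is estimated by phase correlation between the
    cycle's phase-contrast image and the reference cycle's, then applied to
    the cycle's tag, post-bleach and phase images.  Out-of-frame pixels are
    filled with 0; the per-cycle validity mask marks them.

    Parameters
    ----------
    reference_cycle:
        1-based index of the cycle everything is aligned to.
    max_shift:
        Estimated shifts larger than this (in px, per axis magnitude) flag the
        cycle as failed.
    on_failure:
        ``"error"`` raises; ``"drop"`` removes the cycle from the output.
    upsample_factor:
        >1 enables subpixel refinement of the phase correlation.

    Returns
    -------
    (registered run, shift table) where the shift table has one record per
    input cycle: ``{"index", "marker", "shift_y", "shift_x", "failed"}``.
    """
    if len(run.cycles) < 2:
        raise ValueError("registration needs at least two cycles")
    ref = next((c for c in run.cycles if c.index == reference_cycle), None)
    if ref is None:
        raise ValueError(f"reference cycle {reference_cycle} not in run")
    if on_failure not in ("error", "drop"):
        raise ValueError("on_failure must be 'error' or 'drop'")

    out_cycles: list[MelcCycle] = []
    records: list[dict] = []
    for cyc in run.cycles:
        if cyc is ref:
            shift = np.zeros(2)
        else:
            shift, _, _ = phase_cross_correlation(
                ref.phase_image.astype(np.float64),
                cyc.phase_image.astype(np.float64),
                upsample_factor=upsample_factor,
                normalization=None,
            )
        failed = bool(np.max(np.abs(shift)) > max_shift)
        records.append(
            {
                "index": cyc.index,
                "marker": cyc.marker,
                "shift_y": float(shift[0]),
                "shift_x": float(shift[1]),
                "failed": failed,
            }
        )
        if failed:
            if on_failure == "error":
                raise RegistrationError(
                    f"registration failed for cycle {cyc.index} ({cyc.marker}): "
                    f"|shift| {np.max(np.abs(shift)):.1f} px exceeds max_shift={max_shift}"
                )
            warnings.warn(f"dropping cycle {cyc.index} ({cyc.marker}): registration failed")
            continue
        if np.all(shift == 0):
            out_cycles.append(cyc)
        else:
            out_cycles.append(
                replace(
                    cyc,
                    tag_image=_apply_shift(cyc.tag_image, shift),
                    postbleach_image=_apply_shift(cyc.postbleach_image, shift),
                    phase_image=_apply_shift(cyc.phase_image, shift),
                )
            )
    return replace(run, cycles=out_cycles), records


def flat_field_correct(
    image: np.ndarray,
    calibration: CalibrationImages,
    eps: float | None = None,
) -> np.ndarray:
    """Remove the fixed illumination pattern captured by the calibration images.

    ``corrected = (image - dark) / max(bright - dark, eps) * mean(bright - dark)``
    with negatives clipped to 0.  The rescaling by the mean preserves the
    input's intensity scale.  ``eps`` defaults to 1e-6 of the brightfield
    dynamic range and guards isolated pixels where bright <= dark.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != calibration.brightfield.shape:
        raise ValueError("image and calibration shapes differ")
    illum = calibration.brightfield - calibration.darkframe
    if eps is None:
        eps = 1e-6 * max(float(np.ptp(calibration.brightfield)), 1.0)
    denom = np.maximum(illum, eps)
    corrected = (image - calibration.darkframe) / denom * illum.mean()
    return np.clip(corrected, 0.0, None)


def subtract_bleach(tag_image: np.ndarray, postbleach_prev: np.ndarray | None) -> np.ndarray:
    """Subtract the previous cycle's post-bleach image from this cycle's tag image.

    The first cycle has no preceding post-bleach image and passes through
    unchanged.  The difference is clipped at 0.
    """
    tag_image = np.asarray(tag_image, dtype=np.float64)
    if postbleach_prev is None:
        return tag_image.copy()
    postbleach_prev = np.asarray(postbleach_prev, dtype=np.float64)
    if tag_image.shape != postbleach_prev.shape:
        raise ValueError("tag and post-bleach shapes differ")
    return np.clip(tag_image - postbleach_prev, 0.0, None)


class InsufficientImagesError(RuntimeError):
    pass


def estimate_gain(
    images: list[np.ndarray],
    smoothing_scale: float = 50.0,
    min_images: int = 8,
) -> GainField:
    """Estimate a multiplicative shading (vignetting) field from an image stack.

    Retrospective single-gain model: every image is assumed to be
    ``gain(x, y) * signal + noise`` with the same smooth gain.  The per-pixel
    median across the stack is dominated by the (spatially stationary)
    background and scales with the gain; heavy Gaussian smoothing removes the
    residual structure of the foreground.  The result is mean-normalized.
    """
    if len(images) < min_images:
        raise InsufficientImagesError(
            f"gain estimation needs >= {min_images} images, got {len(images)}"
        )
    stack = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    med = np.median(stack, axis=0)
    smooth = ndimage.gaussian_filter(med, smoothing_scale, mode="nearest")
    floor = 1e-6 * max(float(smooth.max()), 1e-12)
    smooth = np.maximum(smooth, floor)
    return GainField(smooth / smooth.mean())


def correct_vignetting(
    images: list[np.ndarray],
    smoothing_scale: float = 50.0,
    min_images: int = 8,
    gain: GainField | None = None,
) -> tuple[list[np.ndarray], GainField]:
    """Divide a stack of images by a common gain field.

    If ``gain`` is not supplied it is estimated from the stack with
    :func:`estimate_gain`; a precomputed map (e.g. from a larger joint stack
    or an external shading-estimation tool) can be passed instead.
    """
    if gain is None:
        gain = estimate_gain(images, smoothing_scale=smoothing_scale, min_images=min_images)
    corrected = [np.asarray(im, dtype=np.float64) / gain.gain for im in images]
    return corrected, gain


def correct_run(
    run: MelcRun,
    register: bool = True,
    reference_cycle: int = 1,
    max_shift: float = 50.0,
    flat_field: bool = True,
    vignetting: bool = True,
    smoothing_scale: float = 50.0,
    min_images: int = 8,
    gain: GainField | None = None,
    eps: float | None = None,
) -> tuple[MelcRun, dict]:
    """Run the full correction chain on an acquisition.

    Order: registration -> flat-field -> post-bleach subtraction ->
    vignetting.  Returns the corrected run (tag images replaced by corrected
    signal images) and a report dict with the shift table and gain field.

    When vignetting estimation is enabled but the stack is too small, the
    images pass through with a warning instead of failing the run.
    """
    report: dict = {"shifts": None, "gain": None}
    if register and len(run.cycles) >= 2:
        run, shifts = register_run(
            run, reference_cycle=reference_cycle, max_shift=max_shift, on_failure="error"
        )
        report["shifts"] = shifts

    if flat_field:
        if run.calibration is None:
            raise ValueError("flat-field correction requested but run has no calibration")
        cycles = [
            replace(
                c,
                tag_image=flat_field_correct(c.tag_image, run.calibration, eps=eps),
                postbleach_image=flat_field_correct(c.postbleach_image, run.calibration, eps=eps),
            )
            for c in run.cycles
        ]
        run = replace(run, cycles=cycles)

    # bleach subtraction uses the *previous* cycle's post-bleach image
    cycles = []
    prev_pb = None
    for c in run.cycles:
        cycles.append(replace(c, tag_image=subtract_bleach(c.tag_image, prev_pb)))
        prev_pb = c.postbleach_image
    run = replace(run, cycles=cycles)

    if vignetting:
        tags = [c.tag_image for c in run.cycles]
        try:
            corrected, gain_field = correct_vignetting(
                tags, smoothing_scale=smoothing_scale, min_images=min_images, gain=gain
            )
        except InsufficientImagesError as err:
            warnings.warn(f"vignetting correction skipped: {err}")
        else:
            run = replace(
                run,
                cycles=[replace(c, tag_image=t) for c, t in zip(run.cycles, corrected)],
            )
            report["gain"] = gain_field
    return run, report
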
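"""Chemometric pretreatments for NIR absorbance spectra.

A spectra matrix is a pandas DataFrame: rows are samples (index = sample ids),
columns are wavelengths in nm (float, strictly increasing).  Supported steps:

* ``SG(window, degree)`` — Savitzky–Golay local polynomial smoothing.
* ``D1`` / ``D2`` — first/second derivative, realised as the corresponding
  Savitzky–Golay derivative filter (same window/degree); plain finite
  differences are available via ``method="diff"``.
* ``MSC`` — multiplicative scatter correction: each spectrum is regressed on a
  reference spectrum (default: the column mean), and the fitted offset and
  slope are removed, x' = (x − b)/a.
* ``MC`` — mean centering: every wavelength column gets mean zero.

Pipelines are written left-to-right, e.g. ``"SG(5,2)+D1+MSC+MC"``, matching
the order of application.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "PretreatmentError",
    "SGStep",
    "DerivativeStep",
    "MSCStep",
    "MeanCenterStep",
    "PretreatmentPipeline",
    "parse_pipeline",
    "savitzky_golay",
    "derivative",
    "msc",
    "mean_center",
    "apply_pipeline",
    "read_spectra_csv",
    "write_spectra_csv",
]


class PretreatmentError(ValueError):
    """Invalid pretreatment parameters or degenerate input."""


def _check_matrix(m: pd.DataFrame) -> pd.DataFrame:
    if m.ndim != 2 or m.shape[1] < 2:
        raise PretreatmentError("spectra matrix needs at least 2 wavelength columns")
    if m.isna().any().any():
        raise PretreatmentError("spectra matrix contains missing values")
    grid = np.asarray(m.columns, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise PretreatmentError("wavelength grid must be strictly increasing")
    return m


def savitzky_golay(
    m: pd.DataFrame,
    window: int = 5,
    degree: int = 2,
    deriv: int = 0,
    delta: float | str = 1.0,
) -> pd.DataFrame:
    """Savitzky–Golay smoothing / differentiation along the wavelength axis.

    ``delta`` is the abscissa step used to scale derivatives: ``1.0`` treats
    channels as unit-spaced (the default; pure rescaling is immaterial once
    features are standardised), ``"nm"`` uses the mean wavelength spacing so
    derivatives come out per nm.  Edges are handled by evaluating the local
    polynomial fitted to the first/last full window (no row shortening).
    """
    m = _check_matrix(m)
    if window % 2 == 0 or window <= degree:
        raise PretreatmentError(
            f"window must be odd and > degree (got window={window}, degree={degree})"
        )
    if not 0 <= deriv <= degree:
        raise PretreatmentError(f"deriv={deriv} must satisfy 0 <= deriv <= degree")
    if m.shape[1] < window:
        raise PretreatmentError(
            f"row length {m.shape[1]} shorter than window {window}"
        )
    if delta == "nm":
        delta = float(np.diff(np.asarray(m.columns, dtype=float)).mean())
    out = savgol_filter(
        m.to_numpy(dtype=float),
        window_length=window,
        polyorder=degree,
        deriv=deriv,
        delta=float(delta),
        axis=1,
        mode="interp",
    )
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def derivative(
    m: pd.DataFrame,
    order: int = 1,
    window: int = 5,
    degree: int = 2,
    delta: float | str = 1.0,
    method: str = "sg",
) -> pd.DataFrame:
    """First or second spectral derivative (Savitzky–Golay by default)."""
    if order not in (1, 2):
        raise PretreatmentError("derivative order must be 1 or 2")
    if method == "sg":
        return savitzky_golay(m, window=window, degree=degree, deriv=order, delta=delta)
    if method == "diff":
        m = _check_matrix(m)
        step = 1.0 if delta != "nm" else float(
            np.diff(np.asarray(m.columns, dtype=float)).mean()
        )
        vals = m.to_numpy(dtype=float)
        for _ in range(order):
            vals = np.gradient(vals, step, axis=1)
        return pd.DataFrame(vals, index=m.index, columns=m.columns)
    raise PretreatmentError(f"unknown derivative method {method!r}")


def msc(
    m: pd.DataFrame, reference: pd.Series | np.ndarray | str = "mean"
) -> pd.DataFrame:
    """Multiplicative scatter correction against a reference spectrum.

    Each row i is modelled as ``x_i = b_i + a_i * ref`` by ordinary least
    squares; the corrected row is ``(x_i − b_i) / a_i``.  With the default
    ``reference="mean"`` the column-mean spectrum of ``m`` itself is used.
    """
    m = _check_matrix(m)
    if isinstance(reference, str):
        if reference != "mean":
            raise PretreatmentError(f"unknown reference {reference!r}")
        if m.shape[0] < 2:
            raise PretreatmentError("mean reference needs at least 2 samples")
        ref = m.to_numpy(dtype=float).mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (m.shape[1],):
            raise PretreatmentError("reference length does not match wavelength grid")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 0.0:
        raise PretreatmentError("reference spectrum has zero variance")
    x = m.to_numpy(dtype=float)
    a = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom  # per-row slope
    if np.any(a == 0.0):
        raise PretreatmentError("a spectrum is uncorrelated with the reference (slope 0)")
    b = x.mean(axis=1) - a * ref.mean()
    out = (x - b[:, None]) / a[:, None]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def mean_center(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract each wavelength column's mean."""
    m = _check_matrix(m)
    if m.shape[0] < 2:
        warnings.warn(
            "mean centering a single spectrum yields all zeros", stacklevel=2
        )
    return m - m.mean(axis=0)


# --------------------------------------------------------------------------
# pipelines


@dataclass(frozen=True)
class SGStep:
    window: int = 5
    degree: int = 2

    def signature(self) -> str:
        if (self.window, self.degree) == (5, 2):
            return "SG"
        return f"SG({self.window},{self.degree})"


@dataclass(frozen=True)
class DerivativeStep:
    order: int  # 1 or 2

    def signature(self) -> str:
        return f"D{self.order}"


@dataclass(frozen=True)
class MSCStep:
    def signature(self) -> str:
        return "MSC"


@dataclass(frozen=True)
class MeanCenterStep:
    def signature(self) -> str:
        return "MC"


Step = SGStep | DerivativeStep | MSCStep | MeanCenterStep


@dataclass(frozen=True)
class PretreatmentPipeline:
    """Ordered pretreatment steps, applied left to right.

    Derivative steps reuse the window/degree of the pipeline's SG step (if
    any), matching the usual "SG+D1" naming convention.
    """

    steps: tuple[Step, ...] = field(default_factory=tuple)

    def signature(self) -> str:
        return "+".join(s.signature() for s in self.steps) if self.steps else "raw"

    def _sg_params(self) -> tuple[int, int]:
        for s in self.steps:
            if isinstance(s, SGStep):
                return s.window, s.degree
        return 5, 2


_STEP_RE = re.compile(r"^SG(?:\((\d+)\s*,\s*(\d+)\))?$")


def parse_pipeline(spec: str) -> PretreatmentPipeline:
    """Parse a signature string like ``"SG(5,2)+D1+MSC+MC"``.

    ``"raw"`` or the empty string give the identity pipeline.
    """
    spec = spec.strip()
    if spec in ("", "raw"):
        return PretreatmentPipeline()
    steps: list[Step] = []
    for token in spec.split("+"):
        token = token.strip()
        sg = _STEP_RE.match(token)
        if sg:
            if sg.group(1) is not None:
                steps.append(SGStep(int(sg.group(1)), int(sg.group(2))))
            else:
                steps.append(SGStep())
        elif token in ("D1", "D2"):
            steps.append(DerivativeStep(int(token[1])))
        elif token == "MSC":
            steps.append(MSCStep())
        elif token == "MC":
            steps.append(MeanCenterStep())
        else:
            raise PretreatmentError(f"unknown pipeline step {token!r} in {spec!r}")
    return PretreatmentPipeline(tuple(steps))


def apply_pipeline(m: pd.DataFrame, pipeline: PretreatmentPipeline | str) -> pd.DataFrame:
    """Apply steps left to right; the result carries the pipeline signature
    in ``DataFrame.attrs["pipeline"]``."""
    if isinstance(pipeline, str):
        pipeline = parse_pipeline(pipeline)
    out = _check_matrix(m)
    window, degree = pipeline._sg_params()
    for i, step in enumerate(pipeline.steps):
        try:
            if isinstance(step, SGStep):
                out = savitzky_golay(out, step.window, step.degree, deriv=0)
            elif isinstance(step, DerivativeStep):
                out = derivative(out, step.order, window=window, degree=degree)
            elif isinstance(step, MSCStep):
                out = msc(out)
            elif isinstance(step, MeanCenterStep):
                out = mean_center(out)
            else:  # pragma: no cover - exhaustive
                raise PretreatmentError(f"unknown step {step!r}")
        except PretreatmentError as exc:
            raise PretreatmentError(
                f"step {i + 1} ({step.signature()}) failed: {exc}"
            ) from exc
    out = out.copy()
    out.attrs["pipeline"] = pipeline.signature()
    return out


# --------------------------------------------------------------------------
# I/O


def read_spectra_csv(path: str | Path) -> pd.DataFrame:
    """Read a spectra CSV: first column sample_id, remaining columns nm."""
    df = pd.read_csv(path, index_col=0)
    try:
        df.columns = df.columns.astype(float)
    except (TypeError, ValueError) as exc:
        raise PretreatmentError("wavelength headers must be numeric (nm)") from exc
    return _check_matrix(df)


def write_spectra_csv(m: pd.DataFrame, path: str | Path) -> None:
    out = m.copy()
    out.index.name = "sample_id"
    out.to_csv(path)
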
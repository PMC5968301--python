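"""Reading, preprocessing, QC and peak picking of raw MALDI-TOF spectra.

This module is the open replacement for the vendor preprocessing chain:
baseline subtraction (SNIP iterative clipping), Savitzky-Golay smoothing,
flat-line / outlier elimination, and SNR-thresholded peak picking.  All
preprocessing operates on the intensity axis only; the m/z axis is never
modified.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "RawSpectrum",
    "PeakList",
    "QCReport",
    "read_spectrum",
    "write_csv",
    "write_mzml",
    "read_mzml",
    "subtract_baseline",
    "smooth",
    "qc_spectrum",
    "detect_peaks",
    "preprocess",
]

# Default analysed mass range for whole-cell MALDI-TOF biotyping (Da).
DEFAULT_MASS_RANGE = (2000.0, 20000.0)


class SpectrumFormatError(ValueError):
    """Raised when an input file does not parse in the declared dialect."""


@dataclass
class RawSpectrum:
    """A continuous m/z-intensity trace with acquisition metadata.

    ``acquisition_index`` distinguishes the repeated reads taken from one
    target spot (several acquisition intervals per biological replicate).
    """

    mz: np.ndarray
    intensity: np.ndarray
    isolate_id: str = ""
    replicate_id: str = ""
    acquisition_index: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class PeakList:
    """Discrete (m/z, intensity) peaks from one spectrum.

    Intensities are normalized so the strongest peak is 1.0.
    """

    mz: np.ndarray
    intensity: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z must be strictly increasing")
        if len(self.intensity):
            if np.any(self.intensity <= 0):
                raise ValueError("peak intensities must be positive")
            top = self.intensity.max()
            if not np.isclose(top, 1.0):
                raise ValueError("peak intensities must be normalized to max 1.0")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class QCReport:
    flat_line: bool
    outlier: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# I/O


def _parse_two_column_table(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectrumFormatError(f"could not parse {path}: {exc}") from exc
    # Optional single header row: drop it if the first row is non-numeric.
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: expected two numeric columns")
    vals = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    bad = vals.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SpectrumFormatError(f"{path}: non-numeric value in data row {row}")
    mz = vals.iloc[:, 0].to_numpy(float)
    inten = vals.iloc[:, 1].to_numpy(float)
    neg = np.flatnonzero(inten < 0)
    if len(neg):
        raise SpectrumFormatError(f"{path}: negative intensity in data row {int(neg[0])}")
    return mz, inten


def read_spectrum(path, format: str | None = None, **meta) -> RawSpectrum:
    """Read one spectrum from a two-column CSV/TSV or an mzML file.

    Unsorted input is sorted by m/z with intensities carried along.  Extra
    keyword arguments become RawSpectrum metadata fields.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "csv"
    if format == "mzml":
        spectra = read_mzml(path)
        if not spectra:
            raise SpectrumFormatError(f"{path}: no spectra found")
        s = spectra[0]
        return replace(s, **meta) if meta else s
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    mz, inten = _parse_two_column_table(path)
    order = np.argsort(mz, kind="stable")
    return RawSpectrum(mz[order], inten[order], **meta)


def write_csv(s: RawSpectrum, path) -> None:
    pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(path, index=False)


_MZML_HEADER = (
    '<?xml version="1.0" encoding="utf-8"?>\n'
    '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
    '  <cvList count="1">\n'
    '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
    ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
    "  </cvList>\n"
    '  <run id="run1">\n'
)


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, float))
    return base64.b64encode(raw).decode("ascii")


def _binary_array_xml(values: np.ndarray, kind: str) -> str:
    enc = _encode_array(values)
    if kind == "mz":
        name = ('<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""'
                ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>')
    else:
        name = ('<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""'
                ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>')
    return (
        f'          <binaryDataArray encodedLength="{len(enc)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f"            {name}\n"
        f"            <binary>{enc}</binary>\n"
        "          </binaryDataArray>\n"
    )


def write_mzml(spectra: Sequence[RawSpectrum] | RawSpectrum, path) -> None:
    """Write spectra to a minimal uncompressed 64-bit mzML file.

    The output carries the m/z and intensity arrays plus the acquisition
    metadata (encoded in the spectrum id) and is readable by standard mzML
    parsers.
    """
    if isinstance(spectra, RawSpectrum):
        spectra = [spectra]
    parts = [_MZML_HEADER, f'    <spectrumList count="{len(spectra)}">\n']
    from urllib.parse import quote

    for i, s in enumerate(spectra):
        sid = escape(
            f"isolate={quote(s.isolate_id)} replicate={quote(s.replicate_id)} "
            f"acquisition={s.acquisition_index} scan={i + 1}",
            {'"': "&quot;"},
        )
        parts.append(
            f'      <spectrum index="{i}" id="{sid}" defaultArrayLength="{len(s)}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>\n'
            '        <binaryDataArrayList count="2">\n'
        )
        parts.append(_binary_array_xml(s.mz, "mz"))
        parts.append(_binary_array_xml(s.intensity, "intensity"))
        parts.append("        </binaryDataArrayList>\n      </spectrum>\n")
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    Path(path).write_text("".join(parts))


def _meta_from_id(sid: str) -> dict:
    from urllib.parse import unquote

    meta: dict = {}
    for token in sid.split():
        if "=" not in token:
            continue
        key, _, val = token.partition("=")
        if key == "isolate":
            meta["isolate_id"] = unquote(val)
        elif key == "replicate":
            meta["replicate_id"] = unquote(val)
        elif key == "acquisition":
            try:
                meta["acquisition_index"] = int(val)
            except ValueError:
                pass
    return meta


_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    import zlib

    accessions = {cv.get("accession") for cv in bda.iter()
                  if cv.tag.endswith("cvParam")}
    kind = ("mz" if _ACC_MZ_ARRAY in accessions
            else "intensity" if _ACC_INT_ARRAY in accessions else None)
    dtype = "<f4" if _ACC_F32 in accessions else "<f8"
    binary = next((el for el in bda.iter() if el.tag.endswith("}binary")), None)
    if binary is None or not (binary.text or "").strip():
        return kind, np.empty(0)
    raw = base64.b64decode(binary.text.strip())
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[RawSpectrum]:
    """Read all spectra from an mzML file.

    Minimal schema-level reader: uncompressed or zlib base64 arrays,
    32- or 64-bit floats, namespace-agnostic.
    """
    from lxml import etree

    out = []
    for _, spec in etree.iterparse(str(path),
                                   tag="{http://psi.hupo.org/ms/mzml}spectrum"):
        mz = inten = None
        for bda in spec.iter("{http://psi.hupo.org/ms/mzml}binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        if mz is None or inten is None:
            continue
        order = np.argsort(mz, kind="stable")
        out.append(RawSpectrum(mz[order], inten[order],
                               **_meta_from_id(spec.get("id", ""))))
        spec.clear()
    return out


# ---------------------------------------------------------------------------
# Preprocessing


def subtract_baseline(s: RawSpectrum, half_window: int = 40, iterations: int = 1) -> RawSpectrum:
    """Remove a slowly varying baseline by SNIP-style iterative clipping.

    The baseline estimate starts as the spectrum itself; for clipping
    windows m = 1..half_window each point is replaced by
    min(b[i], (b[i-m] + b[i+m]) / 2), and the whole sweep is repeated
    ``iterations`` times.  Features narrower than the window survive the
    subtraction; constant and linear trends are removed exactly.
    """
    if half_window < 1 or iterations < 1:
        raise ValueError("half_window and iterations must be >= 1")
    n = len(s)
    if n < 2 * half_window + 1:
        raise ValueError(
            f"spectrum of length {n} too short for half_window {half_window}"
        )
    b = s.intensity.copy()
    for _ in range(iterations):
        for m in range(1, half_window + 1):
            avg = 0.5 * (b[: n - 2 * m] + b[2 * m:])
            np.minimum(b[m: n - m], avg, out=b[m: n - m])
    cleaned = np.maximum(s.intensity - b, 0.0)
    return replace(s, intensity=cleaned)


def smooth(s: RawSpectrum, window: int = 11, polyorder: int = 3) -> RawSpectrum:
    """Savitzky-Golay polynomial smoothing of the intensity trace."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    sm = savgol_filter(s.intensity, window, polyorder)
    return replace(s, intensity=np.maximum(sm, 0.0))


def _binned_vector(s: RawSpectrum, lo: float, hi: float, width: float = 1.0) -> np.ndarray:
    nbins = max(1, int(np.ceil((hi - lo) / width)))
    keep = (s.mz >= lo) & (s.mz < hi)
    vec, _ = np.histogram(s.mz[keep], bins=nbins, range=(lo, hi), weights=s.intensity[keep])
    return vec


def qc_spectrum(
    s: RawSpectrum,
    cohort: Iterable[RawSpectrum],
    *,
    min_peaks: int = 10,
    dynamic_range_floor: float = 0.01,
    correlation_cutoff: float = 0.5,
    snr: float = 3.0,
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
) -> QCReport:
    """Flat-line and outlier elimination of a replicate spectrum.

    A spectrum is flat-lined when its relative dynamic range falls below
    ``dynamic_range_floor`` or fewer than ``min_peaks`` peaks are detectable
    at the given SNR.  It is an outlier when its mean Pearson correlation to
    the other cohort members, on 1-Da binned profiles, falls below
    ``correlation_cutoff``.  Flags are independent of cohort ordering.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must contain at least one spectrum")
    others = [c for c in cohort if c is not s]
    reasons = []

    top = s.intensity.max() if len(s) else 0.0
    if top <= 0 or (top - s.intensity.min()) / top < dynamic_range_floor:
        flat = True
        reasons.append("dynamic range below floor")
    else:
        n_det = len(detect_peaks(s, snr=snr, min_mz=mass_range[0], max_mz=mass_range[1]))
        flat = n_det < min_peaks
        if flat:
            reasons.append(f"only {n_det} detectable peaks (< {min_peaks})")

    outlier = False
    if others:
        lo, hi = mass_range
        v = _binned_vector(s, lo, hi)
        cors = []
        for other in others:
            w = _binned_vector(other, lo, hi)
            if v.std() == 0 or w.std() == 0:
                cors.append(0.0)
            else:
                cors.append(float(np.corrcoef(v, w)[0, 1]))
        if float(np.mean(cors)) < correlation_cutoff:
            outlier = True
            reasons.append(
                f"mean cohort correlation {np.mean(cors):.3f} < {correlation_cutoff}"
            )
    return QCReport(flat_line=flat, outlier=outlier, reason="; ".join(reasons))


def detect_peaks(
    s: RawSpectrum,
    snr: float = 3.0,
    min_mz: float = DEFAULT_MASS_RANGE[0],
    max_mz: float = DEFAULT_MASS_RANGE[1],
    min_rel_intensity: float = 0.01,
) -> PeakList:
    """Pick local maxima exceeding ``snr`` times the MAD-based noise level.

    Noise is estimated as the median absolute deviation of the intensity
    trace scaled to a Gaussian sigma.  Candidates below
    ``min_rel_intensity`` of the tallest candidate are discarded (smoothed
    correlated noise produces shallow maxima that can clear a pure SNR bar
    in an otherwise sparse spectrum).  The result is restricted to
    [min_mz, max_mz] and re-normalized so the strongest peak is 1.0; output
    is invariant to a positive rescaling of the input intensities.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if min_mz >= max_mz:
        raise ValueError("min_mz must be below max_mz")
    x = s.intensity
    if not len(x) or x.max() <= 0:
        return PeakList(np.empty(0), np.empty(0), source=_source_meta(s))
    med = np.median(x)
    sigma = 1.4826 * np.median(np.abs(x - med))
    # Relative floor keeps numerically flat (noise-free) spectra from
    # yielding spurious zero-height maxima.
    height = max(snr * sigma, 1e-9 * x.max())
    idx, _ = find_peaks(x, height=height, prominence=0.5 * height)
    keep = (s.mz[idx] >= min_mz) & (s.mz[idx] <= max_mz)
    idx = idx[keep]
    if len(idx) and min_rel_intensity > 0:
        idx = idx[x[idx] >= min_rel_intensity * x[idx].max()]
    if not len(idx):
        return PeakList(np.empty(0), np.empty(0), source=_source_meta(s))
    inten = x[idx] / x[idx].max()
    return PeakList(s.mz[idx], inten, source=_source_meta(s))


def _source_meta(s: RawSpectrum) -> dict:
    return {
        "isolate_id": s.isolate_id,
        "replicate_id": s.replicate_id,
        "acquisition_index": s.acquisition_index,
    }


def preprocess(
    s: RawSpectrum,
    *,
    half_window: int = 40,
    iterations: int = 1,
    window: int = 11,
    polyorder: int = 3,
    snr: float = 3.0,
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
) -> PeakList:
    """Smooth, baseline-subtract and peak-pick one raw spectrum.

    Smoothing precedes the SNIP subtraction: a clipped baseline estimated
    on the raw trace hugs the lower noise envelope and leaves a positive
    residue that peak picking would mistake for signal.
    """
    cleaned = subtract_baseline(smooth(s, window, polyorder), half_window, iterations)
    return detect_peaks(cleaned, snr=snr, min_mz=mass_range[0], max_mz=mass_range[1])
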
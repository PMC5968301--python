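"""Main spectral profile (MSP) construction and the spectral library store.

An MSP is the consensus reference entry built from replicate peak lists of
one isolate: peaks are clustered across replicates on the m/z axis, each
cluster's occurrence frequency is recorded, and only peaks present in more
than a configurable fraction of the replicates (default: strictly more than
75%) are retained.  Libraries are stored as versioned JSON.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import PeakList

__all__ = [
    "MainSpectralProfile",
    "SpectralLibrary",
    "MSPValidationReport",
    "build_msp",
    "validate_msp",
    "save_library",
    "load_library",
]

SCHEMA_VERSION = "1.0"

# Stringency defaults for database construction: at least 10 contributing
# spectra per entry, peak frequency strictly greater than 75%, and a
# self-identification log score above 2.7 for every contributing spectrum.
DEFAULT_MIN_SPECTRA = 10
DEFAULT_FREQ_FLOOR = 0.75
DEFAULT_SELF_SCORE = 2.7
DEFAULT_MZ_TOLERANCE = 2.0


class LibraryIntegrityError(ValueError):
    pass


class LibraryVersionError(ValueError):
    pass


@dataclass
class MainSpectralProfile:
    """Consensus peak set with per-peak occurrence frequencies."""

    entry_name: str
    genus: str = ""
    species: str = ""
    strain: str = ""
    is_type_strain: bool = False
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    frequency: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_spectra: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        self.frequency = np.asarray(self.frequency, float)
        if not (len(self.mz) == len(self.intensity) == len(self.frequency)):
            raise ValueError("mz, intensity and frequency must have equal length")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("MSP peak m/z must be strictly increasing")
        if len(self.frequency) and (np.any(self.frequency <= 0) or np.any(self.frequency > 1)):
            raise ValueError("frequencies must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.mz)

    def as_peaklist(self) -> PeakList:
        """View the MSP's consensus peaks as a query-able PeakList."""
        return PeakList(self.mz.copy(), self.intensity.copy(),
                        source={"entry_name": self.entry_name})


@dataclass
class SpectralLibrary:
    entries: list[MainSpectralProfile] = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION
    created: str = ""

    def __post_init__(self) -> None:
        names = [e.entry_name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LibraryIntegrityError(f"duplicate entry names: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, entry_name: str) -> MainSpectralProfile:
        for e in self.entries:
            if e.entry_name == entry_name:
                return e
        raise KeyError(entry_name)


@dataclass
class MSPValidationReport:
    per_spectrum_scores: list[tuple[str, float]]
    threshold: float
    all_pass: bool


def build_msp(
    replicates: Sequence[PeakList],
    *,
    entry_name: str = "",
    genus: str = "",
    species: str = "",
    strain: str = "",
    is_type_strain: bool = False,
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
    freq_floor: float = DEFAULT_FREQ_FLOOR,
    min_spectra: int = DEFAULT_MIN_SPECTRA,
) -> MainSpectralProfile:
    """Build a consensus MSP from replicate peak lists.

    Peaks pooled over all replicates are chained into clusters by
    single-linkage on the m/z axis (adjacent peaks closer than
    ``mz_tolerance`` join one cluster).  A cluster's frequency is the
    fraction of replicates contributing at least one member; clusters with
    frequency strictly greater than ``freq_floor`` are kept.  The consensus
    m/z is the intensity-weighted mean of cluster members and the consensus
    intensity the plain mean, re-normalized to a maximum of 1.0.  The result
    is independent of the order of the replicate lists.
    """
    replicates = list(replicates)
    n = len(replicates)
    if n < min_spectra:
        raise ValueError(
            f"MSP construction requires at least {min_spectra} spectra, got {n}"
        )
    mz_all, int_all, rep_all = [], [], []
    for rep_idx, pl in enumerate(replicates):
        mz_all.append(pl.mz)
        int_all.append(pl.intensity)
        rep_all.append(np.full(len(pl), rep_idx))
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    rep = np.concatenate(rep_all)
    order = np.argsort(mz, kind="stable")
    mz, inten, rep = mz[order], inten[order], rep[order]

    out_mz, out_int, out_freq = [], [], []
    if len(mz):
        breaks = np.flatnonzero(np.diff(mz) > mz_tolerance) + 1
        for chunk in np.split(np.arange(len(mz)), breaks):
            members = rep[chunk]
            freq = len(np.unique(members)) / n
            if freq > freq_floor:
                w = inten[chunk]
                out_mz.append(float(np.average(mz[chunk], weights=w)))
                out_int.append(float(np.mean(w)))
                out_freq.append(freq)
    out_mz = np.asarray(out_mz)
    out_int = np.asarray(out_int)
    out_freq = np.asarray(out_freq)
    if len(out_int):
        out_int = out_int / out_int.max()
    srt = np.argsort(out_mz, kind="stable")
    return MainSpectralProfile(
        entry_name=entry_name,
        genus=genus,
        species=species,
        strain=strain,
        is_type_strain=is_type_strain,
        mz=out_mz[srt],
        intensity=out_int[srt],
        frequency=out_freq[srt],
        n_spectra=n,
        provenance={
            "mz_tolerance": mz_tolerance,
            "freq_floor": freq_floor,
            "min_spectra": min_spectra,
            "frequency_denominator": "contributing peak lists",
            "source_spectra": [dict(pl.source) for pl in replicates],
        },
    )


def validate_msp(
    msp: MainSpectralProfile,
    replicates: Sequence[PeakList],
    threshold: float = DEFAULT_SELF_SCORE,
    *,
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
    freq_weighted: bool = True,
) -> MSPValidationReport:
    """Score each contributing spectrum against its own MSP.

    Every contributing spectrum must exceed the self-score threshold
    (default 2.7) for the entry to pass database QC.
    """
    from .identify import score  # local import to avoid a cycle

    replicates = list(replicates)
    if not replicates:
        raise ValueError("no replicates to validate")
    scores = []
    for i, pl in enumerate(replicates):
        sid = str(pl.source.get("replicate_id", i))
        hit = score(pl, msp, mz_tolerance=mz_tolerance, freq_weighted=freq_weighted)
        scores.append((sid, hit.log_score))
    all_pass = all(v > threshold for _, v in scores)
    return MSPValidationReport(per_spectrum_scores=scores, threshold=threshold,
                               all_pass=all_pass)


# ---------------------------------------------------------------------------
# JSON persistence


def _entry_to_json(e: MainSpectralProfile) -> dict:
    return {
        "entry_name": e.entry_name,
        "genus": e.genus,
        "species": e.species,
        "strain": e.strain,
        "is_type_strain": e.is_type_strain,
        "peaks": [
            {"mz": float(m), "intensity": float(i), "frequency": float(f)}
            for m, i, f in zip(e.mz, e.intensity, e.frequency)
        ],
        "n_spectra": e.n_spectra,
        "provenance": e.provenance,
    }


def _entry_from_json(d: dict) -> MainSpectralProfile:
    peaks = d.get("peaks", [])
    return MainSpectralProfile(
        entry_name=d["entry_name"],
        genus=d.get("genus", ""),
        species=d.get("species", ""),
        strain=d.get("strain", ""),
        is_type_strain=bool(d.get("is_type_strain", False)),
        mz=np.array([p["mz"] for p in peaks], float),
        intensity=np.array([p["intensity"] for p in peaks], float),
        frequency=np.array([p["frequency"] for p in peaks], float),
        n_spectra=int(d.get("n_spectra", 0)),
        provenance=d.get("provenance", {}),
    )


def save_library(lib: SpectralLibrary, path) -> None:
    doc = {
        "schema_version": lib.schema_version,
        "created": lib.created or _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "entries": [_entry_to_json(e) for e in lib.entries],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_library(path) -> SpectralLibrary:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LibraryVersionError(f"not a valid library file: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise LibraryVersionError(
            f"unsupported library schema {version!r} (expected {SCHEMA_VERSION})"
        )
    entries = [_entry_from_json(d) for d in doc.get("entries", [])]
    return SpectralLibrary(entries=entries, schema_version=version,
                           created=doc.get("created", ""))
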
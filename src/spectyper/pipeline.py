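"""End-to-end orchestration: simulate -> preprocess -> build database ->
identify -> CCI -> dendrogram -> 16S -> concordance.

Stage outputs are plain files (JSON/TSV/newick) so any stage can be run or
verified in isolation; every report embeds the resolved configuration and
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import concordance as conc
from . import identify as ident
from . import marker_gene as mg
from . import msp as msplib
from . import similarity as sim
from . import spectra as sp
from .synthetic import Scenario, ScenarioConfig, generate_scenario

__all__ = ["PipelineConfig", "run_pipeline", "build_library_from_spectra",
           "identify_isolates"]


@dataclass
class PipelineConfig:
    """All stage parameters with the study defaults."""

    # preprocessing
    baseline_half_window: int = 40
    baseline_iterations: int = 1
    smooth_window: int = 11
    smooth_polyorder: int = 3
    snr: float = 3.0
    mass_range: tuple[float, float] = (2000.0, 20000.0)
    # database stringency
    min_spectra: int = 10
    freq_floor: float = 0.75
    self_score: float = 2.7
    mz_tolerance: float = 2.0
    # identification rubric
    id_threshold: float = 2.2
    min_replicates: int = 3
    n_replicates: int = 4
    genus_threshold: float | None = None
    # CCI / dendrogram
    cci_intervals: int = 10
    cci_mass_lo: float = 3000.0
    cci_mass_hi: float = 12000.0
    cci_bin_width: float = 3.0
    # 16S
    otu_similarity: float = 0.99
    species_identity: float = 98.7
    genus_identity: float = 95.0
    # scenario
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 <= self.freq_floor < 1.0):
            raise ValueError("freq_floor must lie in [0, 1)")
        if not (0.0 <= self.id_threshold <= 3.0 and 0.0 <= self.self_score <= 3.0):
            raise ValueError("log-score thresholds must lie in [0, 3]")
        if self.scenario.seed != self.seed:
            self.scenario = dataclasses.replace(self.scenario, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _preprocess_many(spectra: Sequence[sp.RawSpectrum], cfg: PipelineConfig,
                     qc: bool = True) -> list[sp.PeakList]:
    cleaned = [
        sp.subtract_baseline(
            sp.smooth(s, cfg.smooth_window, cfg.smooth_polyorder),
            cfg.baseline_half_window, cfg.baseline_iterations)
        for s in spectra
    ]
    if qc and len(cleaned) > 1:
        kept = []
        for s in cleaned:
            rep = sp.qc_spectrum(s, cleaned, snr=cfg.snr, mass_range=cfg.mass_range)
            if not (rep.flat_line or rep.outlier):
                kept.append(s)
        # QC must not starve the entry below the database minimum.
        if len(kept) >= cfg.min_spectra:
            cleaned = kept
    peaks = [sp.detect_peaks(s, snr=cfg.snr, min_mz=cfg.mass_range[0],
                             max_mz=cfg.mass_range[1]) for s in cleaned]
    return [p for p in peaks if len(p)]


def build_library_from_spectra(
    spectra_by_entry: dict[str, Sequence[sp.RawSpectrum]],
    cfg: PipelineConfig,
    *,
    entry_meta: dict[str, dict] | None = None,
) -> tuple[msplib.SpectralLibrary, list[msplib.MSPValidationReport]]:
    """Preprocess replicate spectra per entry, build and self-validate MSPs."""
    entries = []
    reports = []
    for entry_name in sorted(spectra_by_entry):
        meta = (entry_meta or {}).get(entry_name, {})
        if not meta:
            parsed = conc.parse_entry_name(entry_name)
            meta = {"genus": parsed.genus, "species": parsed.species,
                    "strain": parsed.strain, "is_type_strain": parsed.is_type_strain}
        peaks = _preprocess_many(spectra_by_entry[entry_name], cfg)
        entry = msplib.build_msp(
            peaks, entry_name=entry_name, mz_tolerance=cfg.mz_tolerance,
            freq_floor=cfg.freq_floor, min_spectra=cfg.min_spectra, **meta)
        reports.append(msplib.validate_msp(entry, peaks, cfg.self_score,
                                           mz_tolerance=cfg.mz_tolerance))
        entries.append(entry)
    return msplib.SpectralLibrary(entries=entries), reports


def identify_isolates(
    spectra_by_isolate: dict[str, Sequence[sp.RawSpectrum]],
    lib: msplib.SpectralLibrary,
    cfg: PipelineConfig,
) -> list[ident.IdentificationCall]:
    """Preprocess each isolate's replicates and apply the consensus rubric."""
    calls = []
    for iso in sorted(spectra_by_isolate):
        rep_hits: dict[str, list[ident.ScoredHit]] = {}
        for s in spectra_by_isolate[iso]:
            pl = sp.preprocess(
                s, half_window=cfg.baseline_half_window,
                iterations=cfg.baseline_iterations, window=cfg.smooth_window,
                polyorder=cfg.smooth_polyorder, snr=cfg.snr,
                mass_range=cfg.mass_range)
            if not len(pl):
                continue
            rep_hits[s.replicate_id or f"rep{len(rep_hits)}"] = ident.rank(
                pl, lib, cfg.mz_tolerance)
        if not rep_hits:
            calls.append(ident.IdentificationCall(
                isolate_id=iso, replicate_results=[], level="unidentified"))
            continue
        calls.append(ident.consensus_call(
            rep_hits, isolate_id=iso, threshold=cfg.id_threshold,
            min_replicates=cfg.min_replicates,
            genus_threshold=cfg.genus_threshold))
    return calls


def _calls_table(calls: Sequence[ident.IdentificationCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "isolate_id": c.isolate_id,
            "level": c.level,
            "entry_name": c.entry_name or "",
            "genus": c.genus or "",
            "score": round(c.score, 3),
        })
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig | None = None, out_dir=None) -> dict:
    """Run the full synthetic-scenario pipeline; return the summary report.

    When ``out_dir`` is given, every stage's table plus the summary (with
    the resolved config and seed) is written there.
    """
    cfg = cfg or PipelineConfig()
    scn: Scenario = generate_scenario(cfg.scenario)

    # Database construction with self-validation
    lib, reports = build_library_from_spectra(scn.library_spectra, cfg)
    validation_pass = sum(r.all_pass for r in reports)

    # Real-time-classification analogue on the unknowns
    calls = identify_isolates(scn.unknown_spectra, lib, cfg)
    calls_df = _calls_table(calls).merge(scn.truth, on="isolate_id")

    def correct_species(row) -> bool:
        if row["level"] != "species":
            return False
        p = conc.parse_entry_name(row["entry_name"])
        return conc.species_match(p, conc.parse_entry_name(row["binomial"]))

    calls_df["correct"] = calls_df.apply(correct_species, axis=1)
    in_lib = calls_df[calls_df["in_library"]]
    out_lib = calls_df[~calls_df["in_library"]]
    recovery = float(in_lib["correct"].mean()) if len(in_lib) else float("nan")
    novel_rate = (float((out_lib["level"] == "unidentified").mean())
                  if len(out_lib) else float("nan"))

    # Strain-level CCI
    strain_peaks = {
        sid: _preprocess_many(spectra, cfg, qc=False)
        for sid, spectra in scn.strain_spectra.items()
    }
    cci_mat = sim.cci_matrix(
        strain_peaks, mass_lo=cfg.cci_mass_lo, mass_hi=cfg.cci_mass_hi,
        bin_width=cfg.cci_bin_width, n_intervals=cfg.cci_intervals)
    labels = cci_mat.labels
    same = []
    diff = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            v = cci_mat.values[i, j]
            if scn.strain_species[labels[i]] == scn.strain_species[labels[j]]:
                same.append(v)
            else:
                diff.append(v)
    cci_within = float(np.mean(same)) if same else float("nan")
    cci_between = float(np.mean(diff)) if diff else float("nan")

    # MSP dendrogram
    newick, merge_table = sim.msp_dendrogram(
        lib, mass_lo=cfg.mass_range[0], mass_hi=cfg.mass_range[1],
        bin_width=cfg.cci_bin_width)

    # 16S layer
    tax_calls = [mg.classify_16s(q, scn.refs_16s,
                                 species_identity=cfg.species_identity,
                                 genus_identity=cfg.genus_identity)
                 for q in scn.queries_16s]
    tax_df = pd.DataFrame([{
        "isolate_id": t.query_id, "best_ref": t.best_ref_id,
        "identity": round(t.percent_identity, 3), "level": t.level,
    } for t in tax_calls])

    # Concordance of the two methods (species-level 16S records only, as in
    # the partition arithmetic)
    typed = [e.entry_name for e in lib if e.is_type_strain]
    call_by_iso = {c.isolate_id: c for c in calls}
    records = []
    for t in tax_calls:
        if t.level != "species":
            continue
        c = call_by_iso[t.query_id]
        sp16 = conc.parse_entry_name(t.best_ref_id).binomial
        records.append(conc.categorize(
            t.query_id, sp16, t.percent_identity,
            c.entry_name or "", c.score,
            registry=scn.registry, threshold=cfg.id_threshold,
            typed_species=typed, maldi_level=c.level))
    counts = conc.tabulate(records)

    summary = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_library_entries": len(lib),
        "msp_validation_pass": int(validation_pass),
        "n_unknowns": int(len(calls_df)),
        "species_recovery_in_library": recovery,
        "unidentified_rate_out_of_library": novel_rate,
        "cci_within_species_mean": cci_within,
        "cci_between_species_mean": cci_between,
        "concordance_counts": counts,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        msplib.save_library(lib, out / "library.json")
        calls_df.to_csv(out / "identifications.tsv", sep="\t", index=False)
        cci_mat.save_tsv(out / "cci_matrix.tsv")
        (out / "msp_dendrogram.nwk").write_text(newick + "\n")
        merge_table.to_csv(out / "msp_dendrogram_merges.tsv", sep="\t", index=False)
        tax_df.to_csv(out / "taxonomy_16s.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            out / "concordance.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
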
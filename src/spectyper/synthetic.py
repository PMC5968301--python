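"""Ground-truthed synthetic spectra and 16S sequence sets.

The generator emulates the statistical structure the analysis assumes,
without claiming instrument realism: each species carries a latent peak
fingerprint in the 2,000-20,000 m/z range; replicate spectra render those
peaks as Gaussians with Bernoulli per-peak dropout, m/z jitter, log-normal
intensity noise, a smooth baseline and additive Gaussian noise.  Strain
variants perturb a few peaks of their parent fingerprint.  16S sets
include a "taxonomic group" of species whose sequences are >=99.9%
identical while their spectral fingerprints are unrelated.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .concordance import TaxGroupRegistry, default_registry
from .marker_gene import Seq16S, write_fasta
from .spectra import RawSpectrum, write_mzml

__all__ = [
    "LatentFingerprint",
    "NoiseModel",
    "ScenarioConfig",
    "Scenario",
    "make_fingerprint",
    "derive_strain",
    "simulate_spectrum",
    "simulate_replicates",
    "simulate_16s",
    "make_taxgroup_16s",
    "generate_scenario",
    "build_scenario",
]

_BASES = np.array(list("ACGT"))


@dataclass
class LatentFingerprint:
    """A species' latent proteomic fingerprint: peak positions, base
    intensities and per-replicate occurrence probabilities."""

    species: str
    mz: np.ndarray
    intensity: np.ndarray
    occurrence: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        self.occurrence = np.asarray(self.occurrence, float)
        if not (len(self.mz) == len(self.intensity) == len(self.occurrence)):
            raise ValueError("fingerprint arrays must have equal length")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("fingerprint m/z must be increasing")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class NoiseModel:
    """Replicate-to-replicate acquisition noise.

    mz_jitter_sd       m/z jitter per rendered peak (Da)
    intensity_cv       log-normal coefficient of variation of peak heights
    baseline_amplitude amplitude of the smooth (exponential-decay) baseline
    noise_sd           additive Gaussian noise sigma (intensity units)
    peak_width         Gaussian peak sigma (Da)
    peak_width_sd      replicate variation of the peak sigma (Da)
    """

    mz_jitter_sd: float = 1.0
    intensity_cv: float = 0.25
    baseline_amplitude: float = 0.1
    noise_sd: float = 0.003
    peak_width: float = 3.0
    peak_width_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mz_jitter_sd", "intensity_cv", "baseline_amplitude",
                     "noise_sd", "peak_width", "peak_width_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def make_fingerprint(
    n_peaks: int,
    rng,
    *,
    species: str = "",
    mass_range: tuple[float, float] = (2000.0, 20000.0),
    min_spacing: float | None = None,
    peak_width: float = 3.0,
    intensity_range: tuple[float, float] = (0.1, 1.0),
    occurrence_range: tuple[float, float] = (0.85, 1.0),
) -> LatentFingerprint:
    """Draw a fingerprint of peaks uniform over the mass range.

    Peaks keep a minimum spacing (default three peak FWHMs, i.e. ~7 sigma)
    so rendered Gaussians of unequal height remain resolvable as separate
    maxima.  Deterministic given the rng state.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    rng = _rng(rng)
    lo, hi = mass_range
    spacing = 3.0 * 2.3548 * peak_width if min_spacing is None else min_spacing
    if n_peaks * spacing >= (hi - lo):
        raise ValueError("mass range cannot hold n_peaks at the minimum spacing")
    positions: list[float] = []
    attempts = 0
    while len(positions) < n_peaks:
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - p) >= spacing for p in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 1000 * n_peaks:
            raise ValueError("could not place peaks at the requested spacing")
    order = np.argsort(positions)
    mz = np.asarray(positions)[order]
    inten = rng.uniform(*intensity_range, size=n_peaks)
    occ = rng.uniform(*occurrence_range, size=n_peaks)
    return LatentFingerprint(species=species, mz=mz, intensity=inten, occurrence=occ)


def derive_strain(
    parent: LatentFingerprint,
    n_changes: int,
    rng,
    *,
    mass_range: tuple[float, float] = (2000.0, 20000.0),
    min_spacing: float = 21.0,
) -> LatentFingerprint:
    """Perturb ``n_changes`` peaks of the parent fingerprint.

    Each change removes a peak, adds a new one, or shifts one peak's base
    intensity; the remainder of the fingerprint is identical to the parent.
    """
    if n_changes >= len(parent):
        raise ValueError("n_changes must be below the number of parent peaks")
    rng = _rng(rng)
    mz = list(parent.mz)
    inten = list(parent.intensity)
    occ = list(parent.occurrence)
    for _ in range(n_changes):
        op = rng.choice(["remove", "add", "shift"])
        if op == "remove" and len(mz) > 1:
            i = int(rng.integers(len(mz)))
            mz.pop(i); inten.pop(i); occ.pop(i)
        elif op == "add":
            for _ in range(1000):
                cand = float(rng.uniform(*mass_range))
                if all(abs(cand - p) >= min_spacing for p in mz):
                    mz.append(cand)
                    inten.append(float(rng.uniform(0.1, 1.0)))
                    occ.append(float(rng.uniform(0.85, 1.0)))
                    break
        else:
            i = int(rng.integers(len(mz)))
            inten[i] = float(np.clip(inten[i] * rng.uniform(0.25, 4.0), 0.05, 1.0))
    order = np.argsort(mz)
    return LatentFingerprint(
        species=parent.species,
        mz=np.asarray(mz)[order],
        intensity=np.asarray(inten)[order],
        occurrence=np.asarray(occ)[order],
    )


def simulate_spectrum(
    fp: LatentFingerprint,
    noise: NoiseModel,
    rng=None,
    *,
    grid_step: float = 1.0,
    mass_range: tuple[float, float] = (2000.0, 20000.0),
    isolate_id: str = "",
    replicate_id: str = "",
    acquisition_index: int = 0,
) -> RawSpectrum:
    """Render one replicate spectrum of a fingerprint on a regular grid.

    Each latent peak is included with its occurrence probability and drawn
    as a Gaussian at jittered m/z with log-normally perturbed height; an
    exponential-decay baseline and additive Gaussian noise complete the
    trace.  Bit-identical on rerun with the same seed.
    """
    rng = _rng(noise.seed if rng is None else rng)
    lo, hi = mass_range
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    trace = np.zeros_like(grid)
    sigma_ln = np.sqrt(np.log(1.0 + noise.intensity_cv ** 2))
    for m, a, p in zip(fp.mz, fp.intensity, fp.occurrence):
        present = rng.random() < p
        center = m + rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else m
        amp = a * rng.lognormal(0.0, sigma_ln) if sigma_ln else a
        width = noise.peak_width + (rng.normal(0.0, noise.peak_width_sd)
                                    if noise.peak_width_sd else 0.0)
        width = max(0.5, width)
        if not present:
            continue
        i0 = np.searchsorted(grid, center - 6 * width)
        i1 = np.searchsorted(grid, center + 6 * width)
        window = grid[i0:i1]
        trace[i0:i1] += amp * np.exp(-0.5 * ((window - center) / width) ** 2)
    if noise.baseline_amplitude:
        trace += noise.baseline_amplitude * np.exp(-(grid - lo) / (0.25 * (hi - lo)))
    if noise.noise_sd:
        trace += rng.normal(0.0, noise.noise_sd, size=grid.shape)
    np.maximum(trace, 0.0, out=trace)
    return RawSpectrum(grid, trace, isolate_id=isolate_id,
                       replicate_id=replicate_id, acquisition_index=acquisition_index)


def simulate_replicates(
    fp: LatentFingerprint,
    noise: NoiseModel,
    rng,
    *,
    n_bio: int = 8,
    n_acq: int = 3,
    isolate_id: str = "",
    **kwargs,
) -> list[RawSpectrum]:
    """Replicate design of database acquisition: ``n_bio`` biological
    replicates (target spots), each read in ``n_acq`` acquisition intervals."""
    rng = _rng(rng)
    out = []
    for b in range(n_bio):
        for a in range(n_acq):
            out.append(simulate_spectrum(
                fp, noise, rng, isolate_id=isolate_id,
                replicate_id=f"rep{b + 1:02d}", acquisition_index=a + 1, **kwargs))
    return out


# ---------------------------------------------------------------------------
# 16S sequence simulation


def _random_sequence(length: int, rng) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(seq: str, n_subs: int, rng) -> str:
    if n_subs > len(seq):
        raise ValueError("divergence exceeds sequence length")
    arr = np.array(list(seq))
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_16s(
    divergences: Sequence[int],
    rng,
    *,
    length: int = 1400,
    ids: Sequence[str] | None = None,
    ancestor: str | None = None,
) -> list[Seq16S]:
    """Derive one sequence per requested substitution count from an ancestor.

    A single substitution on a 1,400-base gene leaves ~99.93% identity to
    the ancestor; ~100 substitutions drop below the 95% genus threshold.
    """
    rng = _rng(rng)
    if any(d < 0 for d in divergences):
        raise ValueError("divergences must be non-negative")
    if ancestor is None:
        ancestor = _random_sequence(length, rng)
    if ids is None:
        ids = [f"seq{i:02d}" for i in range(len(divergences))]
    return [Seq16S(sid, _mutate(ancestor, int(d), rng))
            for sid, d in zip(ids, divergences)]


def make_taxgroup_16s(
    n_members: int,
    rng,
    *,
    length: int = 1400,
    ids: Sequence[str] | None = None,
    ancestor: str | None = None,
) -> list[Seq16S]:
    """Sequences of a taxonomic group: pairwise identity >= (length-1)/length.

    All members differ from each other at a single shared position, so four
    members of a 1,400-base gene are pairwise >=99.9% identical — the
    structure that makes the group unresolvable by 16S identity alone.
    """
    if not 2 <= n_members <= 4:
        raise ValueError("a single-position group supports 2-4 members")
    rng = _rng(rng)
    if ancestor is None:
        ancestor = _random_sequence(length, rng)
    if ids is None:
        ids = [f"member{i}" for i in range(n_members)]
    pos = int(rng.integers(length))
    variants = [ancestor[pos]] + [b for b in "ACGT" if b != ancestor[pos]]
    out = []
    for i in range(n_members):
        seq = ancestor[:pos] + variants[i] + ancestor[pos + 1:]
        out.append(Seq16S(ids[i], seq))
    return out


# ---------------------------------------------------------------------------
# Full study scenario


@dataclass
class ScenarioConfig:
    """Counts and noise of the default synthetic study.

    Mirrors the study design: 20 library species including one 4-member
    taxonomic group and one species with 7 strain variants; MSPs built from
    8 biological replicates x 3 acquisitions; unknowns identified from 4
    biological replicates; 5 additional species absent from the library.
    """

    n_species: int = 20
    taxgroup_size: int = 4
    strain_species_index: int = 4
    n_strains: int = 7
    strain_spectra_each: int = 3
    strain_changes: int = 4
    n_out_of_library: int = 5
    n_peaks: int = 30
    n_bio_replicates: int = 8
    n_acquisitions: int = 3
    n_unknown_replicates: int = 4
    seq_length: int = 1400
    species_divergence: tuple[int, int] = (25, 60)
    out_of_library_divergence: tuple[int, int] = (60, 100)
    noise: NoiseModel = field(default_factory=NoiseModel)
    grid_step: float = 1.0
    mass_range: tuple[float, float] = (2000.0, 20000.0)
    seed: int = 7


@dataclass
class SpeciesTruth:
    genus: str
    epithet: str
    entry_name: str
    in_library: bool
    fingerprint: LatentFingerprint
    sequence: Seq16S

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.epithet}"


@dataclass
class Scenario:
    config: ScenarioConfig
    species: list[SpeciesTruth]
    library_spectra: dict[str, list[RawSpectrum]]
    unknown_spectra: dict[str, list[RawSpectrum]]
    strain_spectra: dict[str, list[RawSpectrum]]
    strain_species: dict[str, str]
    refs_16s: list[Seq16S]
    queries_16s: list[Seq16S]
    truth: pd.DataFrame
    registry: TaxGroupRegistry


_TAXGROUP_EPITHETS = ["pumilus", "safensis", "australimaris", "zhangzhouensis"]
_STRAIN_EPITHET = "firmus"


def _species_names(cfg: ScenarioConfig) -> list[tuple[str, str]]:
    names: list[tuple[str, str]] = []
    for i in range(cfg.n_species):
        if i < cfg.taxgroup_size:
            names.append(("Bacillus", _TAXGROUP_EPITHETS[i % 4]))
        elif i == cfg.strain_species_index:
            names.append(("Bacillus", _STRAIN_EPITHET))
        else:
            names.append(("Bacillus", f"simspecies{i:02d}"))
    for j in range(cfg.n_out_of_library):
        names.append(("Bacillus", f"novelspecies{j:02d}"))
    return names


def generate_scenario(cfg: ScenarioConfig | None = None) -> Scenario:
    """Generate the full in-memory study scenario from (config, seed)."""
    cfg = cfg or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    names = _species_names(cfg)
    n_total = len(names)

    # Latent fingerprints: independent per species (taxonomic-group members
    # share 16S, not spectra — that is the point of the contrast).
    fingerprints = [
        make_fingerprint(cfg.n_peaks, rng, species=f"{g} {e}",
                         mass_range=cfg.mass_range,
                         peak_width=cfg.noise.peak_width)
        for g, e in names
    ]

    # 16S: one global ancestor; the taxonomic group sits on a single
    # shared variable position; everything else diverges independently.
    ancestor = _random_sequence(cfg.seq_length, rng)
    group_ancestor = _mutate(ancestor, 30, rng)
    group_seqs = make_taxgroup_16s(
        cfg.taxgroup_size, rng, length=cfg.seq_length, ancestor=group_ancestor,
        ids=[f"{g}_{e}" for g, e in names[: cfg.taxgroup_size]])
    seqs: list[Seq16S] = list(group_seqs)
    for i in range(cfg.taxgroup_size, n_total):
        lo, hi = (cfg.species_divergence if i < cfg.n_species
                  else cfg.out_of_library_divergence)
        div = int(rng.integers(lo, hi + 1))
        g, e = names[i]
        seqs.append(simulate_16s([div], rng, length=cfg.seq_length,
                                 ids=[f"{g}_{e}"], ancestor=ancestor)[0])

    species: list[SpeciesTruth] = []
    for i, ((g, e), fp, sq) in enumerate(zip(names, fingerprints, seqs)):
        in_lib = i < cfg.n_species
        entry = f"{g} {e}_TS{i:02d}^T" if in_lib else ""
        species.append(SpeciesTruth(g, e, entry, in_lib, fp, sq))

    # Library acquisition: 8 spots x 3 reads per type-strain isolate.
    library_spectra: dict[str, list[RawSpectrum]] = {}
    for sp in species[: cfg.n_species]:
        library_spectra[sp.entry_name] = simulate_replicates(
            sp.fingerprint, cfg.noise, rng,
            n_bio=cfg.n_bio_replicates, n_acq=cfg.n_acquisitions,
            isolate_id=sp.entry_name, grid_step=cfg.grid_step,
            mass_range=cfg.mass_range)

    # Unknown isolates: one per species, identified in 4 biological replicates.
    unknown_spectra: dict[str, list[RawSpectrum]] = {}
    truth_rows = []
    queries_16s: list[Seq16S] = []
    for sp in species:
        iso = f"UNK_{sp.epithet}"
        reps = []
        for b in range(cfg.n_unknown_replicates):
            reps.append(simulate_spectrum(
                sp.fingerprint, cfg.noise, rng, grid_step=cfg.grid_step,
                mass_range=cfg.mass_range, isolate_id=iso,
                replicate_id=f"rep{b + 1:02d}", acquisition_index=1))
        unknown_spectra[iso] = reps
        queries_16s.append(Seq16S(iso, _mutate(sp.sequence.sequence, 1, rng)))
        truth_rows.append({"isolate_id": iso, "genus": sp.genus,
                           "species": sp.epithet, "binomial": sp.binomial,
                           "in_library": sp.in_library})

    # Strain panel of the strain-rich species plus an unrelated outgroup
    # species, for the CCI contrast.
    strain_spectra: dict[str, list[RawSpectrum]] = {}
    strain_species: dict[str, str] = {}
    focal = species[cfg.strain_species_index]
    outgroup = species[cfg.n_species - 1]
    for s in range(cfg.n_strains):
        sid = f"{focal.epithet}_strain{s + 1:02d}"
        fp = derive_strain(focal.fingerprint, cfg.strain_changes, rng,
                           mass_range=cfg.mass_range)
        strain_spectra[sid] = [
            simulate_spectrum(fp, cfg.noise, rng, grid_step=cfg.grid_step,
                              mass_range=cfg.mass_range, isolate_id=sid,
                              replicate_id=f"rep{k + 1:02d}")
            for k in range(cfg.strain_spectra_each)]
        strain_species[sid] = focal.binomial
    for s in range(2):
        sid = f"{outgroup.epithet}_strain{s + 1:02d}"
        fp = derive_strain(outgroup.fingerprint, cfg.strain_changes, rng,
                           mass_range=cfg.mass_range)
        strain_spectra[sid] = [
            simulate_spectrum(fp, cfg.noise, rng, grid_step=cfg.grid_step,
                              mass_range=cfg.mass_range, isolate_id=sid,
                              replicate_id=f"rep{k + 1:02d}")
            for k in range(cfg.strain_spectra_each)]
        strain_species[sid] = outgroup.binomial

    refs = [Seq16S(f"{sp.genus}_{sp.epithet}_TS{i:02d}^T", sp.sequence.sequence)
            for i, sp in enumerate(species) if sp.in_library]

    return Scenario(
        config=cfg,
        species=species,
        library_spectra=library_spectra,
        unknown_spectra=unknown_spectra,
        strain_spectra=strain_spectra,
        strain_species=strain_species,
        refs_16s=refs,
        queries_16s=queries_16s,
        truth=pd.DataFrame(truth_rows),
        registry=default_registry(),
    )


def build_scenario(cfg: ScenarioConfig | None = None, out_dir=".") -> dict:
    """Write the scenario to disk and return the manifest.

    Spectra go to mzML (one file per isolate), sequences to FASTA, the
    truth table to TSV, the taxonomic-group registry to YAML, and the
    manifest to JSON.
    """
    import json

    cfg = cfg or ScenarioConfig()
    scn = generate_scenario(cfg)
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "files": {}}

    def slug(name: str) -> str:
        return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)

    lib_files = {}
    for entry, spectra in scn.library_spectra.items():
        p = out / "spectra" / f"lib_{slug(entry)}.mzML"
        write_mzml(spectra, p)
        lib_files[entry] = p.name
    unk_files = {}
    for iso, spectra in scn.unknown_spectra.items():
        p = out / "spectra" / f"unk_{slug(iso)}.mzML"
        write_mzml(spectra, p)
        unk_files[iso] = p.name
    strain_files = {}
    for sid, spectra in scn.strain_spectra.items():
        p = out / "spectra" / f"strain_{slug(sid)}.mzML"
        write_mzml(spectra, p)
        strain_files[sid] = p.name

    write_fasta(scn.refs_16s, out / "type_strains_16s.fasta")
    write_fasta(scn.queries_16s, out / "queries_16s.fasta")
    scn.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    scn.registry.to_yaml(out / "taxgroups.yaml")

    manifest["files"] = {
        "library_spectra": lib_files,
        "unknown_spectra": unk_files,
        "strain_spectra": strain_files,
        "refs_16s": "type_strains_16s.fasta",
        "queries_16s": "queries_16s.fasta",
        "truth": "truth.tsv",
        "registry": "taxgroups.yaml",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
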
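"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator takes an immutable spec carrying an explicit seed (no global
random state) and returns both the object a real experiment would provide
and the ground truth a real experiment withholds:

- :func:`gen_trace` — an extracted-ion-chromatogram: Gaussian elution peak
  over baseline plus zero-clipped Gaussian noise within an m/z window.
- :func:`gen_stack` — a two-channel confocal z-stack: hard-edged ellipsoidal
  nuclei (nuclear-stain channel) and a signal channel carrying a requested
  nuclear fraction of total intensity, followed by Gaussian blur and noise.
- :func:`gen_proteins` — random protein sequences with a motif planted at
  known positions; non-planted sequences are rejection-sampled until
  motif-free, so the positive count is exact.
- :func:`gen_expression_sets` — two transcript-ID sets with exact sizes and
  overlap drawn from a finite universe.
- :func:`gen_psm_table` — a PSM table in which each row's pass/fail status
  against the evidence filters is fixed by construction.

Default parameter values describe the experiments the pipeline was designed
around: a ~1e6-intensity peptide XIC sampled at 1 Hz, fields of ~5 flattened
myocyte-like nuclei imaged at 0.232 µm (xy) / 0.041 µm (z), a 6-member
transcription-factor panel with the motif in 4, and differential-transcript
sets of 800 and 705 IDs sharing 299 out of a 47,000-transcript universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgquant import ImageStack, NuclearMask
from .motifscan import ProteinRecord, find_motif
from .msquant import AMINO_ACIDS, ChromatogramTrace

__all__ = [
    "TraceSpec",
    "StackSpec",
    "ProteomeSpec",
    "ExpressionSetsSpec",
    "gen_trace",
    "gen_stack",
    "gen_proteins",
    "gen_expression_sets",
    "gen_psm_table",
]

_AA_TUPLE = tuple(sorted(AMINO_ACIDS))


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    """Recipe for one synthetic XIC.

    The retention-time grid is uniform: ``rt_start, rt_start + rt_step, ...``
    up to (excluding) ``rt_stop``.  Intensity is
    ``baseline + apex_amplitude * exp(-(t - peak_center)^2 / (2 sigma^2))``
    plus iid Gaussian noise, clipped at zero.
    """

    peak_center: float = 300.0
    peak_width_sigma: float = 8.0
    apex_amplitude: float = 1.3e6
    noise_sd: float = 1.0e4
    baseline: float = 0.0
    mz_window: tuple[float, float] = (509.5, 511.5)
    rt_start: float = 0.0
    rt_stop: float = 600.0
    rt_step: float = 1.0
    sample_id: str = "sample"
    peptide: str = ""
    condition: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_width_sigma <= 0:
            raise ValueError(f"peak_width_sigma must be > 0, got {self.peak_width_sigma}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.apex_amplitude < 0 or self.baseline < 0:
            raise ValueError("apex_amplitude and baseline must be >= 0")
        low, high = self.mz_window
        if not low < high:
            raise ValueError(f"mz_window low must be < high: {self.mz_window}")
        if self.rt_step <= 0 or self.rt_stop <= self.rt_start:
            raise ValueError("retention-time grid must be non-empty and increasing")

    @property
    def retention_times(self) -> np.ndarray:
        n = int(np.floor((self.rt_stop - self.rt_start) / self.rt_step))
        return self.rt_start + self.rt_step * np.arange(n)


def gen_trace(spec: TraceSpec) -> ChromatogramTrace:
    """Render one chromatogram from its spec; bit-identical under a fixed
    spec + seed."""
    times = spec.retention_times
    if times.size == 0:
        raise ValueError("retention-time grid is empty")
    clean = spec.baseline + spec.apex_amplitude * np.exp(
        -((times - spec.peak_center) ** 2) / (2.0 * spec.peak_width_sigma**2)
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        clean = clean + rng.normal(0.0, spec.noise_sd, size=times.size)
    intensities = np.clip(clean, 0.0, None)
    return ChromatogramTrace(
        retention_times=times,
        intensities=intensities,
        mz_window=spec.mz_window,
        sample_id=spec.sample_id,
        peptide=spec.peptide,
        condition=spec.condition,
    )


# ---------------------------------------------------------------------------
# Confocal stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackSpec:
    """Recipe for one two-channel confocal z-stack.

    Nuclei are hard-edged, axis-aligned ellipsoids placed fully inside the
    field without overlap; cytoplasm is an ellipsoidal envelope around each
    nucleus (``cytoplasm_scale`` times the nuclear semi-axes, clipped to the
    field).  The signal channel distributes ``nuclear_fraction`` of its
    pre-noise intensity uniformly over nuclear voxels and the remainder
    uniformly over cytoplasmic voxels.  Both channels are then Gaussian
    blurred (``blur_sigma`` voxels) and carry iid Gaussian noise clipped at
    zero.

    ``nucleus_axes`` are semi-axes in µm, (z, y, x); the default nucleus is
    flattened in z as adherent-cell nuclei are, and the default field is
    sized so the nuclei span nearly the whole z-range (stacks are acquired
    around the nuclei).
    """

    shape: tuple[int, int, int] = (32, 96, 96)
    voxel_size: tuple[float, float, float] = (0.041, 0.232, 0.232)
    n_cells: int = 5
    nuclear_fraction: float = 0.30
    nucleus_axes: tuple[float, float, float] = (0.63, 2.5, 2.5)
    cytoplasm_scale: tuple[float, float, float] = (1.08, 1.8, 1.8)
    nuclear_level: float = 200.0
    background_level: float = 10.0
    signal_level: float = 200.0
    blur_sigma: float = 1.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.nuclear_fraction <= 1.0:
            raise ValueError(
                f"nuclear_fraction must be in [0, 1], got {self.nuclear_fraction}"
            )
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if any(v <= 0 for v in self.voxel_size) or any(a <= 0 for a in self.nucleus_axes):
            raise ValueError("voxel_size and nucleus_axes must be positive")
        if any(s < 1.0 for s in self.cytoplasm_scale):
            raise ValueError("cytoplasm_scale must be >= 1 in every axis")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")

    @property
    def nucleus_axes_vox(self) -> tuple[float, float, float]:
        return tuple(a / v for a, v in zip(self.nucleus_axes, self.voxel_size))  # type: ignore[return-value]


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _place_nuclei(spec: StackSpec, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    Z, Y, X = spec.shape
    az, ay, ax = spec.nucleus_axes_vox
    if 2 * az > Z - 1 or 2 * ay > Y - 1 or 2 * ax > X - 1:
        raise ValueError(
            f"nucleus semi-axes {spec.nucleus_axes} µm do not fit inside the "
            f"field of shape {spec.shape} at voxel size {spec.voxel_size}"
        )
    # nuclei must be fully inside the field and pairwise disjoint
    min_sep = 2.0 * max(ay, ax) + 2.0
    centers: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 200 * spec.n_cells
    while len(centers) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping nuclei in a "
                f"{spec.shape} field after {max_attempts} attempts; reduce "
                "n_cells or nucleus_axes"
            )
        cz = rng.uniform(az, Z - 1 - az)
        cy = rng.uniform(ay + 1, Y - 2 - ay)
        cx = rng.uniform(ax + 1, X - 2 - ax)
        if all(np.hypot(cy - oy, cx - ox) >= min_sep for _, oy, ox in centers):
            centers.append((cz, cy, cx))
    return centers


def gen_stack(
    spec: StackSpec,
) -> tuple[ImageStack, ImageStack, NuclearMask, float]:
    """Render one two-channel stack.

    Returns ``(nuclear_channel, signal_channel, truth_mask,
    realized_fraction)`` where ``realized_fraction`` is recomputed from the
    rendered, pre-noise signal channel against the truth mask (it differs
    from the requested fraction only by the intensity the blur carries
    across the nuclear boundary, well under 0.01 at default settings).
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_nuclei(spec, rng)
    axes = spec.nucleus_axes_vox
    cyto_axes = tuple(a * s for a, s in zip(axes, spec.cytoplasm_scale))

    nuc_mask = np.zeros(spec.shape, dtype=bool)
    cell_mask = np.zeros(spec.shape, dtype=bool)
    for c in centers:
        nuc_mask |= _ellipsoid_mask(spec.shape, c, axes)
        cell_mask |= _ellipsoid_mask(spec.shape, c, cyto_axes)
    cyto_mask = cell_mask & ~nuc_mask
    n_nuc = int(nuc_mask.sum())
    n_cyto = int(cyto_mask.sum())
    if n_nuc == 0:
        raise RuntimeError("degenerate spec: nuclei rendered to zero voxels")

    f = spec.nuclear_fraction
    nuclear_channel = np.where(nuc_mask, spec.nuclear_level, spec.background_level).astype(float)
    if spec.blur_sigma > 0:
        nuclear_channel = ndimage.gaussian_filter(nuclear_channel, spec.blur_sigma)

    # Blur is linear, so render the signal as a * blur(1_nucleus) +
    # c * blur(1_cytoplasm) and solve for the cytoplasmic level c that puts
    # exactly the requested fraction of the *rendered* (post-blur, pre-noise)
    # intensity inside the truth mask.  Without blur this reduces to
    # c = a * n_nuc * (1-f) / (f * n_cyto).
    a = spec.signal_level
    nuc_field = nuc_mask.astype(float)
    cyto_field = cyto_mask.astype(float)
    if spec.blur_sigma > 0:
        nuc_field = ndimage.gaussian_filter(nuc_field, spec.blur_sigma)
        cyto_field = ndimage.gaussian_filter(cyto_field, spec.blur_sigma)
    sn_in = float(nuc_field[nuc_mask].sum())  # nuclear mass staying nuclear
    sc_in = float(cyto_field[nuc_mask].sum())  # cytoplasmic mass leaking in
    sn_tot = float(nuc_field.sum())
    sc_tot = float(cyto_field.sum())

    if f == 0.0:
        signal = a * cyto_field if n_cyto > 0 else np.zeros(spec.shape)
    elif f == 1.0 or n_cyto == 0:
        leak = 1.0 - (sn_in / sn_tot if sn_tot > 0 else 0.0)
        if leak > 0.01:
            raise ValueError(
                f"requested nuclear_fraction {f} is unattainable: blur_sigma "
                f"{spec.blur_sigma} carries {leak:.1%} of the nuclear signal "
                "outside the truth mask; reduce blur_sigma"
            )
        signal = a * nuc_field
    else:
        denom = f * sc_tot - sc_in
        if denom <= 0:
            raise ValueError(
                f"requested nuclear_fraction {f} is below what blur leakage "
                "into the nuclei already provides; reduce blur_sigma or "
                "increase nuclear_fraction"
            )
        c = a * (sn_in - f * sn_tot) / denom
        if c < 0:
            raise ValueError(
                f"requested nuclear_fraction {f} exceeds the share blur can "
                f"retain inside nuclei ({sn_in / sn_tot:.3f}); reduce "
                "blur_sigma or nuclear_fraction"
            )
        signal = a * nuc_field + c * cyto_field

    total = signal.sum()
    realized = float(signal[nuc_mask].sum() / total) if total > 0 else 0.0

    if spec.noise_sd > 0:
        nuclear_channel = nuclear_channel + rng.normal(0.0, spec.noise_sd, spec.shape)
        signal = signal + rng.normal(0.0, spec.noise_sd, spec.shape)
    nuclear_channel = np.clip(nuclear_channel, 0.0, None)
    signal = np.clip(signal, 0.0, None)

    nuclear_stack = ImageStack(
        voxels=nuclear_channel, voxel_size=spec.voxel_size, channel_label="nuclear-stain"
    )
    signal_stack = ImageStack(
        voxels=signal, voxel_size=spec.voxel_size, channel_label="signal"
    )
    truth = NuclearMask(
        voxels=nuc_mask,
        method_record={"method": "ground-truth", "centers": centers, "semi_axes_vox": axes},
    )
    return nuclear_stack, signal_stack, truth, realized


# ---------------------------------------------------------------------------
# Protein panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeSpec:
    """Recipe for a protein panel with a motif planted at known positions.

    ``planted_positions`` maps 0-based protein index to the 0-based start of
    the planted motif; proteins absent from the map are guaranteed
    motif-free by rejection sampling.
    """

    n_proteins: int = 6
    motif_pattern: str = "LLTPPG"
    planted_positions: dict[int, int] = field(default_factory=dict)
    length_range: tuple[int, int] = (200, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.motif_pattern.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"motif pattern contains non-amino-acid symbol(s): "
                f"{', '.join(sorted(bad))}"
            )
        lo, hi = self.length_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        for idx, pos in self.planted_positions.items():
            if not 0 <= idx < self.n_proteins:
                raise ValueError(f"planted protein index {idx} out of range")
            if pos < 0 or pos + len(self.motif_pattern) > lo:
                raise ValueError(
                    f"planted position {pos} + pattern length "
                    f"{len(self.motif_pattern)} exceeds minimum protein length {lo}"
                )


def gen_proteins(spec: ProteomeSpec) -> list[ProteinRecord]:
    """Generate the panel; exactly the planted proteins contain the pattern.

    Non-planted sequences are resampled until they contain no exact
    occurrence of the pattern; planted sequences get the pattern spliced in
    at the requested position.
    """
    rng = np.random.default_rng(spec.seed)
    pattern = spec.motif_pattern.upper()
    aa = np.array(list(_AA_TUPLE))
    records: list[ProteinRecord] = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        for _ in range(1000):
            seq = "".join(rng.choice(aa, size=length))
            if pattern not in seq:
                break
        else:  # pragma: no cover - astronomically unlikely for real patterns
            raise RuntimeError("could not sample a motif-free background sequence")
        if i in spec.planted_positions:
            pos = spec.planted_positions[i]
            seq = seq[:pos] + pattern + seq[pos + len(pattern):]
        records.append(ProteinRecord(id=f"SYN{i:03d}", sequence=seq))
    # construction check: the scan agrees with the plant
    for i, rec in enumerate(records):
        hits = find_motif(rec, pattern=pattern, max_mismatch=0)
        planted = i in spec.planted_positions
        if planted and spec.planted_positions[i] not in [h.start for h in hits]:
            raise RuntimeError(f"planted motif not recovered in protein {i}")
        if not planted and hits:  # pragma: no cover - excluded by resampling
            raise RuntimeError(f"spurious motif in non-planted protein {i}")
    return records


# ---------------------------------------------------------------------------
# Expression sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSetsSpec:
    """Recipe for two overlapping differential-transcript ID sets.

    Defaults mirror a genome-wide profiling comparison: 800 transcripts
    modulated in the control line, 705 after knockdown, 299 shared, drawn
    from a 47,000-transcript universe.
    """

    size_a: int = 800
    size_b: int = 705
    overlap: int = 299
    universe_size: int = 47000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.size_a, self.size_b, self.overlap, self.universe_size) < 0:
            raise ValueError("all counts must be >= 0")
        if self.overlap > min(self.size_a, self.size_b):
            raise ValueError(
                f"overlap {self.overlap} exceeds min(size_a, size_b) = "
                f"{min(self.size_a, self.size_b)}"
            )
        if self.size_a + self.size_b - self.overlap > self.universe_size:
            raise ValueError(
                f"union size {self.size_a + self.size_b - self.overlap} exceeds "
                f"universe_size {self.universe_size}"
            )


def gen_expression_sets(spec: ExpressionSetsSpec) -> tuple[set[str], set[str]]:
    """Two ID sets with exact cardinalities: |A|=size_a, |B|=size_b,
    |A∩B|=overlap."""
    rng = np.random.default_rng(spec.seed)
    union_size = spec.size_a + spec.size_b - spec.overlap
    ids = rng.choice(spec.universe_size, size=union_size, replace=False)
    labels = [f"TR{int(i):06d}" for i in ids]
    shared = labels[: spec.overlap]
    a_only = labels[spec.overlap : spec.overlap + (spec.size_a - spec.overlap)]
    b_only = labels[spec.overlap + (spec.size_a - spec.overlap):]
    return set(shared) | set(a_only), set(shared) | set(b_only)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def _random_tryptic_peptide(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(np.array(list(AMINO_ACIDS - {"K", "R"})), size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def gen_psm_table(
    n_records: int = 200,
    n_proteins: int = 20,
    pass_fraction: float = 0.5,
    min_product_ions: int = 15,
    min_ion_score: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A PSM table whose per-row pass/fail status is fixed by construction.

    Each row is first assigned a true label (``true_pass`` column): passing
    rows draw ``product_ion_count`` and ``ion_score`` at or above the
    thresholds, failing rows are guaranteed below at least one of them.
    Modifications (Met +16 / Cys +57) are placed only on matching residues.
    The ``true_pass`` column is ground truth for testing the evidence
    filters and is not part of the canonical PSM CSV schema.
    """
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValueError("pass_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_records):
        should_pass = rng.random() < pass_fraction
        if should_pass:
            ions = int(rng.integers(min_product_ions, min_product_ions + 20))
            score = float(np.round(rng.uniform(min_ion_score, min_ion_score + 60), 2))
        else:
            mode = rng.integers(3)  # fail on ions, on score, or on both
            ions = (
                int(rng.integers(0, min_product_ions))
                if mode in (0, 2)
                else int(rng.integers(min_product_ions, min_product_ions + 20))
            )
            score = (
                float(np.round(rng.uniform(0, min_ion_score - 0.01), 2))
                if mode in (1, 2)
                else float(np.round(rng.uniform(min_ion_score, min_ion_score + 60), 2))
            )
        peptide = _random_tryptic_peptide(rng, int(rng.integers(8, 16)))
        mods = []
        for pos, res in enumerate(peptide):
            if res == "M" and rng.random() < 0.3:
                mods.append((pos, 15.994915))
            elif res == "C":
                mods.append((pos, 57.021464))
        rows.append(
            {
                "sample_id": "treated" if rng.random() < 0.5 else "control",
                "protein_accession": f"P{int(rng.integers(n_proteins)):03d}",
                "peptide": peptide,
                "charge": int(rng.integers(1, 4)),
                "ion_score": score,
                "product_ion_count": ions,
                "modifications": tuple(mods),
                "validated": bool(rng.random() < 0.8),
                "true_pass": should_pass,
            }
        )
    return pd.DataFrame(rows)
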
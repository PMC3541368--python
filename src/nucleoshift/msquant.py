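"""Label-free MS quantitation of a signature peptide.

The quantitation strategy is the one used to demonstrate nuclear accumulation
of the G-protein beta-2 subunit after angiotensin II stimulation:

1. Peptide-spectrum matches (PSMs) are filtered on evidence quality — at
   least 15 product ions in the MS/MS spectrum and a peptide ion score of at
   least 30 — and a protein is accepted only if it retains at least one
   manually validated signature peptide.
2. Relative protein abundance across samples is summarized by spectrum
   counting (retained PSMs per protein per sample).
3. For the signature peptide itself, an extracted ion chromatogram (XIC) is
   read within an m/z window and quantified by its apex — the "100%
   abundance" value of the chromatogram.
4. The treated/control apex ratio of the target peptide is divided by the
   same ratio for a spiked-in control peptide (trypsin autolysis product),
   yielding a spike-in-normalized fold change.  The worked example is
   2.47 / 0.79 = 3.13.

All thresholds are inclusive.  Apex quantitation is the default; integrated
peak area is available as an opt-in alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "AMINO_ACIDS",
    "ALLOWED_MOD_DELTAS",
    "PsmRecord",
    "FilterCriteria",
    "ChromatogramTrace",
    "FoldChangeResult",
    "filter_psms",
    "spectrum_count",
    "extract_apex",
    "peak_area",
    "abundance_ratio",
    "normalized_fold_change",
    "round_fold",
    "peptide_mz",
    "psms_to_frame",
]

#: The 20 standard amino-acid one-letter codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Variable/fixed modification mass deltas admitted on a PSM, in Da:
#: oxidation of methionine (+16) and carbamidomethylation of cysteine (+57).
#: Both the nominal integer values and the monoisotopic values are accepted.
ALLOWED_MOD_DELTAS = (15.994915, 57.021464, 16.0, 57.0)

_MOD_TOL_DA = 0.5

#: Required columns of a PSM table (one row per peptide-spectrum match).
PSM_COLUMNS = (
    "sample_id",
    "protein_accession",
    "peptide",
    "charge",
    "ion_score",
    "product_ion_count",
    "modifications",
    "validated",
)


def _check_peptide(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(
            f"peptide {sequence!r} contains non-standard residue(s): "
            f"{', '.join(sorted(bad))}"
        )
    return seq


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    ``modifications`` is a sequence of ``(position, mass_delta_da)`` pairs
    with 0-based residue positions; deltas must come from
    :data:`ALLOWED_MOD_DELTAS` (within 0.5 Da). ``validated`` records whether
    the CID spectrum passed manual interpretation — it is an input flag, not
    a computed one.
    """

    sample_id: str
    protein_accession: str
    peptide: str
    charge: int
    ion_score: float
    product_ion_count: int
    modifications: tuple[tuple[int, float], ...] = ()
    validated: bool = False

    def __post_init__(self) -> None:
        _check_peptide(self.peptide)
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.product_ion_count < 0:
            raise ValueError("product_ion_count must be >= 0")
        for pos, delta in self.modifications:
            if not 0 <= pos < len(self.peptide):
                raise ValueError(f"modification position {pos} outside peptide")
            if min(abs(delta - a) for a in ALLOWED_MOD_DELTAS) > _MOD_TOL_DA:
                raise ValueError(
                    f"modification delta {delta} Da not in the allowed set "
                    f"(+16 Met oxidation, +57 Cys carbamidomethylation)"
                )


def psms_to_frame(records: Iterable[PsmRecord]) -> pd.DataFrame:
    """Tabulate :class:`PsmRecord` objects into the canonical PSM DataFrame."""
    rows = [
        {
            "sample_id": r.sample_id,
            "protein_accession": r.protein_accession,
            "peptide": r.peptide,
            "charge": r.charge,
            "ion_score": r.ion_score,
            "product_ion_count": r.product_ion_count,
            "modifications": tuple(r.modifications),
            "validated": r.validated,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(PSM_COLUMNS))


@dataclass(frozen=True)
class FilterCriteria:
    """Evidence thresholds for PSM and protein acceptance (all inclusive).

    Defaults reproduce the published acceptance rules: >=15 product ions,
    ion score >=30, and at least one manually validated signature peptide
    per protein.  The mass tolerances (3.0 Da peptide / 2.0 Da fragment) are
    recorded search-engine settings carried along for provenance; they do
    not re-filter PSMs here because matching happened upstream.
    """

    min_product_ions: int = 15
    min_ion_score: float = 30.0
    min_validated_signature_peptides_per_protein: int = 1
    peptide_mass_tolerance: float = 3.0
    fragment_mass_tolerance: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "min_product_ions",
            "min_ion_score",
            "min_validated_signature_peptides_per_protein",
            "peptide_mass_tolerance",
            "fragment_mass_tolerance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class ChromatogramTrace:
    """An extracted ion chromatogram: intensity vs retention time within an
    m/z window."""

    retention_times: np.ndarray
    intensities: np.ndarray
    mz_window: tuple[float, float]
    sample_id: str = ""
    peptide: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.retention_times.shape != self.intensities.shape:
            raise ValueError("retention_times and intensities differ in length")
        if self.retention_times.size == 0:
            raise ValueError("empty chromatogram")
        if np.any(np.diff(self.retention_times) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        low, high = self.mz_window
        if not low < high:
            raise ValueError(f"mz_window low must be < high, got {self.mz_window}")

    def contains_mz(self, mz: float) -> bool:
        """Inclusive membership test for an m/z value in this trace's window."""
        low, high = self.mz_window
        return low <= mz <= high


@dataclass(frozen=True)
class FoldChangeResult:
    """Spike-in-normalized fold change with its two component ratios."""

    target_ratio: float
    spike_ratio: float
    normalized_fold: float

    @property
    def reported_fold(self) -> float:
        """The fold rounded to two decimals (half away from zero) for
        reporting; computation elsewhere keeps full precision."""
        return round_fold(self.normalized_fold)


# ---------------------------------------------------------------------------
# Filtering and spectrum counting
# ---------------------------------------------------------------------------

def filter_psms(
    psms: pd.DataFrame, criteria: FilterCriteria | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Apply evidence filters to a PSM table.

    A PSM is retained iff ``product_ion_count >= min_product_ions`` and
    ``ion_score >= min_ion_score`` (inclusive).  A protein accession is
    retained iff it has at least
    ``min_validated_signature_peptides_per_protein`` retained PSMs with
    ``validated == True``.

    Returns the retained PSM rows (original order and index preserved) and
    the sorted list of retained protein accessions.
    """
    criteria = criteria or FilterCriteria()
    if psms.empty:
        return psms.copy(), []
    keep = (psms["product_ion_count"] >= criteria.min_product_ions) & (
        psms["ion_score"] >= criteria.min_ion_score
    )
    retained = psms.loc[keep].copy()
    validated = retained.loc[retained["validated"].astype(bool)]
    per_protein = validated.groupby("protein_accession").size()
    proteins = sorted(
        per_protein[
            per_protein >= criteria.min_validated_signature_peptides_per_protein
        ].index
    )
    return retained, proteins


def spectrum_count(psms: pd.DataFrame) -> pd.DataFrame:
    """Spectrum counting: number of PSMs per (protein, sample).

    The sum of counts equals the number of input rows; apply
    :func:`filter_psms` first for counts over retained evidence only.
    """
    if psms.empty:
        return pd.DataFrame(columns=["protein_accession", "sample_id", "count"])
    counts = (
        psms.groupby(["protein_accession", "sample_id"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return counts


# ---------------------------------------------------------------------------
# XIC quantitation
# ---------------------------------------------------------------------------

def _restrict(trace: ChromatogramTrace, rt_range: tuple[float, float] | None):
    if rt_range is None:
        return trace.intensities
    lo, hi = rt_range
    sel = (trace.retention_times >= lo) & (trace.retention_times <= hi)
    if not np.any(sel):
        raise ValueError(
            f"retention-time window {rt_range} contains no data points "
            f"(trace spans {trace.retention_times[0]:g}-"
            f"{trace.retention_times[-1]:g} s)"
        )
    return trace.intensities[sel]


def extract_apex(
    trace: ChromatogramTrace,
    rt_range: tuple[float, float] | None = None,
    subtract_baseline: bool = False,
) -> float:
    """Apex intensity of an XIC — its "100% abundance" value.

    The maximum intensity within ``rt_range`` (whole trace when omitted).
    With ``subtract_baseline`` the minimum intensity of the restricted
    window is subtracted first (off by default; the published procedure
    applies none).
    """
    values = _restrict(trace, rt_range)
    apex = float(values.max())
    if subtract_baseline:
        apex -= float(values.min())
    return apex


def peak_area(
    trace: ChromatogramTrace, rt_range: tuple[float, float] | None = None
) -> float:
    """Opt-in alternative metric: trapezoidal area under the XIC."""
    if rt_range is None:
        times, values = trace.retention_times, trace.intensities
    else:
        lo, hi = rt_range
        sel = (trace.retention_times >= lo) & (trace.retention_times <= hi)
        if not np.any(sel):
            raise ValueError(f"retention-time window {rt_range} is empty")
        times, values = trace.retention_times[sel], trace.intensities[sel]
    return float(np.trapezoid(values, times))


def abundance_ratio(treated_apex: float, control_apex: float) -> float:
    """Between-sample abundance ratio of one peptide: treated apex divided
    by control apex."""
    if control_apex <= 0:
        raise ZeroDivisionError(
            f"abundance ratio undefined: control apex is {control_apex}"
        )
    if treated_apex < 0:
        raise ValueError("treated apex must be non-negative")
    return treated_apex / control_apex


def normalized_fold_change(target_ratio: float, spike_ratio: float) -> float:
    """Spike-in-normalized fold change: the target peptide's abundance ratio
    divided by the spiked-in control peptide's ratio.

    Dividing out the spike-in ratio cancels between-run loading and
    instrument-response differences; the worked example is
    ``2.47 / 0.79 = 3.13`` (reported to two decimals).
    """
    if spike_ratio <= 0:
        raise ZeroDivisionError(
            f"normalization undefined: spike-in ratio is {spike_ratio}"
        )
    return target_ratio / spike_ratio


def round_fold(value: float, decimals: int = 2) -> float:
    """Round half away from zero to ``decimals`` places (reporting only)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def fold_change_from_apexes(
    target_treated: float,
    target_control: float,
    spike_treated: float,
    spike_control: float,
) -> FoldChangeResult:
    """Full-precision fold change from the four apex intensities."""
    tr = abundance_ratio(target_treated, target_control)
    sr = abundance_ratio(spike_treated, spike_control)
    return FoldChangeResult(
        target_ratio=tr, spike_ratio=sr, normalized_fold=normalized_fold_change(tr, sr)
    )


# ---------------------------------------------------------------------------
# Peptide m/z calculator (window sanity checks)
# ---------------------------------------------------------------------------

def peptide_mz(
    sequence: str,
    charge: int,
    mass_mode: Literal["monoisotopic", "average"] = "monoisotopic",
) -> float:
    """m/z of a peptide at a given charge state.

    ``(sum of residue masses + water + charge * proton) / charge`` with
    residue masses in the chosen mode.  Useful for checking that an
    instrument m/z window (e.g. 509.5-511.5 for LLVSASQDGK 2+ in average
    mode) actually covers the peptide.
    """
    seq = _check_peptide(sequence)
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if mass_mode not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass_mode {mass_mode!r}")
    return float(
        _ptmass.calculate_mass(
            sequence=seq, charge=charge, average=(mass_mode == "average")
        )
    )
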
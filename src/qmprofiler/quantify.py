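"""Instrument-readout -> microbial-load conversions and their evaluation.

Covers the three quantification channels used to anchor quantitative
microbiome profiles, plus the arithmetic used to validate them:

* flow cytometry: gated event counts to cells/ml (:func:`events_to_concentration`);
* qPCR: Ct values against a standard curve to copies (:func:`fit_standard_curve`,
  :func:`ct_to_copies`), amplification efficiency, and the
  delta-Ct -> percent-signal-reduction arithmetic used to verify viability
  treatment (:func:`delta_ct_signal_reduction`);
* ddPCR: Poisson quantification from the positive-droplet fraction
  (:func:`ddpcr_concentration`);
* paired untreated/PMA load differencing to estimate the extracellular
  DNA fraction (:func:`estimate_extracellular_fraction`);
* mock-community dilution-series evaluation (:func:`evaluate_mock_series`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


class SaturatedWellError(ValueError):
    """All droplets positive: the well is outside the quantifiable range."""


# ---------------------------------------------------------------------------
# types


@dataclass
class StandardCurve:
    """qPCR standard curve: ``Ct = slope * log10(copies) + intercept``."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("a valid standard curve has negative slope")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, ``10^(-1/slope) - 1``."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class DdpcrWell:
    """One droplet-digital-PCR well readout."""

    droplets_total: int
    droplets_positive: int
    droplet_volume_ul: float = 0.00085  # standard droplet volume for the QX class

    def __post_init__(self) -> None:
        if self.droplets_total <= 0:
            raise ValueError("droplets_total must be positive")
        if not 0 <= self.droplets_positive <= self.droplets_total:
            raise ValueError("droplets_positive outside [0, droplets_total]")
        if self.droplet_volume_ul <= 0:
            raise ValueError("droplet volume must be positive")


@dataclass
class MockCommunitySpec:
    """An even whole-cell mock community with known per-species copy numbers."""

    species: tuple[str, ...]
    copy_numbers: tuple[float, ...]
    expected_cells_per_ml: float

    def __post_init__(self) -> None:
        if len(self.species) != len(self.copy_numbers):
            raise ValueError("species and copy_numbers length mismatch")

    @property
    def average_copy_number(self) -> float:
        return float(np.mean(self.copy_numbers))


#: Synthetic default 12-species gut mock community.  The species list and
#: per-species 16S copy numbers are an illustrative stand-in (the per-strain
#: values of the commercial mix are not published alongside its average);
#: they are chosen so the mean copy number is exactly 6.435 copies/genome,
#: the conversion constant used when translating mock qPCR copies into cells.
DEFAULT_MOCK_COMMUNITY = MockCommunitySpec(
    species=(
        "Bacteroides fragilis", "Bacteroides vulgatus",
        "Bifidobacterium adolescentis", "Clostridioides difficile",
        "Enterobacter cloacae", "Escherichia coli",
        "Faecalibacterium prausnitzii", "Fusobacterium nucleatum",
        "Lactobacillus plantarum", "Enterococcus faecalis",
        "Akkermansia muciniphila", "Salmonella enterica",
    ),
    copy_numbers=(6.0, 7.0, 5.0, 12.0, 8.0, 7.22, 6.0, 5.0, 5.0, 4.0, 3.0, 9.0),
    expected_cells_per_ml=3.3e6,
)


# ---------------------------------------------------------------------------
# flow cytometry


def events_to_concentration(
    events_in_gate: int,
    tube_mass_before_g: float,
    tube_mass_after_g: float,
    dilution_factor: float = 1.0,
    fluid_density_g_per_ml: float = 1.0,
) -> float:
    """Gated event count to cells/ml of the original sample.

    The acquired volume is inferred by weighing the tube before and after
    acquisition; the dilution factor scales back to the undiluted sample:
    ``events / ((m_before - m_after) / density) * dilution``.
    """
    if events_in_gate < 0:
        raise ValueError("events_in_gate must be >= 0")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if fluid_density_g_per_ml <= 0:
        raise ValueError("fluid density must be positive")
    consumed_ml = (tube_mass_before_g - tube_mass_after_g) / fluid_density_g_per_ml
    if consumed_ml <= 0:
        raise ValueError("non-positive acquired volume (check tube masses)")
    return events_in_gate / consumed_ml * dilution_factor


def concentration_to_per_gram(
    cells_per_ml: float, suspension_volume_ml: float, feces_mass_g: float
) -> float:
    """Convert a suspension concentration into cells per gram of input feces."""
    if suspension_volume_ml <= 0 or feces_mass_g <= 0:
        raise ValueError("volume and mass must be positive")
    return cells_per_ml * suspension_volume_ml / feces_mass_g


# ---------------------------------------------------------------------------
# qPCR


def fit_standard_curve(ct_values, known_log10_copies) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies).

    Requires at least three standards spanning more than one concentration.
    A flat (non-negative-slope) fit is rejected: it cannot quantify.
    """
    ct = np.asarray(ct_values, dtype=float)
    x = np.asarray(known_log10_copies, dtype=float)
    if ct.shape != x.shape:
        raise ValueError("ct_values and known_log10_copies length mismatch")
    if ct.size < 3:
        raise ValueError("at least 3 standards are required")
    if np.ptp(x) == 0:
        raise ValueError("standards span a single concentration")
    res = sps.linregress(x, ct)
    if res.slope >= 0:
        raise ValueError("degenerate standard curve (slope >= 0)")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def ct_to_copies(
    curve: StandardCurve,
    ct: float,
    template_dilution: float = 1.0,
    reaction_to_gram_factor: float = 1.0,
) -> float:
    """Invert a standard curve: Ct to 16S copies (per gram with factors).

    ``copies_reaction = 10^((intercept - ct) / |slope|)``; the template
    dilution and the reaction-to-gram scale-up (elution volume, input mass)
    are explicit inputs because they are assay-specific.
    """
    if template_dilution <= 0 or reaction_to_gram_factor <= 0:
        raise ValueError("scale factors must be positive")
    copies_reaction = 10.0 ** ((curve.intercept - ct) / abs(curve.slope))
    return copies_reaction * template_dilution * reaction_to_gram_factor


def copies_to_ct(curve: StandardCurve, copies_reaction: float) -> float:
    """The forward curve: expected Ct for a per-reaction copy number."""
    if copies_reaction <= 0:
        raise ValueError("copies must be positive")
    return curve.slope * math.log10(copies_reaction) + curve.intercept


# ---------------------------------------------------------------------------
# ddPCR


@dataclass
class DdpcrResult:
    copies_per_ul: float
    below_detection: bool = False


def ddpcr_concentration(well: DdpcrWell) -> DdpcrResult:
    """Poisson quantification of a ddPCR well.

    ``lambda = -ln(1 - positives/total)`` copies per droplet, divided by the
    droplet volume.  A fully positive well is a hard error (saturation would
    otherwise be silently clipped and bias loads); a fully negative well
    returns zero flagged as below detection.
    """
    p = well.droplets_positive / well.droplets_total
    if p == 1.0:
        raise SaturatedWellError(
            "all droplets positive; sample too concentrated to quantify"
        )
    if p == 0.0:
        return DdpcrResult(0.0, below_detection=True)
    lam = -math.log1p(-p)
    return DdpcrResult(lam / well.droplet_volume_ul, below_detection=False)


def copies_to_cells_fixed(copies_per_ml: float, average_copy_number: float) -> float:
    """Copies/ml to cells/ml using a fixed community-average copy number."""
    if average_copy_number <= 0:
        raise ValueError("average_copy_number must be positive")
    return copies_per_ml / average_copy_number


# ---------------------------------------------------------------------------
# viability-PCR differencing


@dataclass
class ExtracellularFractionResult:
    """Paired untreated/PMA load differencing summary."""

    fractions: pd.Series
    mean_fraction: float
    mean_absolute_decrease: float
    wilcoxon_statistic: float
    p_value: float


def estimate_extracellular_fraction(untreated, treated) -> ExtracellularFractionResult:
    """Estimate the extracellular DNA fraction from paired loads.

    ``fraction_s = (untreated_s - treated_s) / untreated_s`` per sample; a
    shared multiplicative factor on a pair (e.g. extraction yield when the
    pair shares an aliquot) cancels exactly.  Significance of the decrease
    is assessed with a paired two-sided Wilcoxon signed-rank test.
    """
    from .stats import paired_wilcoxon  # local import avoids a cycle

    u = pd.Series(untreated, dtype=float)
    t = pd.Series(treated, dtype=float)
    if not u.index.equals(t.index):
        t = t.reindex(u.index)
        if t.isna().any():
            missing = list(t.index[t.isna()])
            raise ValueError(f"mismatched pairing keys; missing treated: {missing}")
    if len(u) < 1:
        raise ValueError("at least one complete pair is required")
    if (u <= 0).any() or (t <= 0).any():
        raise ValueError("loads must be positive")
    fractions = (u - t) / u
    test = paired_wilcoxon(u.to_numpy(), t.to_numpy())
    return ExtracellularFractionResult(
        fractions=fractions,
        mean_fraction=float(fractions.mean()),
        mean_absolute_decrease=float((u - t).mean()),
        wilcoxon_statistic=float(test.statistic),
        p_value=float(test.pvalue),
    )


def delta_ct_signal_reduction(delta_ct: float, efficiency: float = 1.0) -> float:
    """Percent signal reduction implied by a Ct increase.

    At efficiency ``E`` each cycle multiplies signal by ``1 + E``, so a Ct
    increase of ``d`` corresponds to ``(1 - (1+E)^-d) * 100`` percent less
    starting template.  A negative delta-Ct is allowed (signal increased)
    but logged, returning a negative reduction.
    """
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    if delta_ct < 0:
        log.warning("negative delta-Ct (%.3f): signal increased", delta_ct)
    return (1.0 - (1.0 + efficiency) ** (-delta_ct)) * 100.0


def signal_reduction_summary(
    delta_cts, efficiency: float = 1.0, mode: str = "mean_delta_ct"
) -> float:
    """Summarize several delta-Ct values into one percent reduction.

    ``mean_delta_ct`` (default) converts the mean Ct shift; ``per_sample``
    averages the per-sample percent reductions instead.  The two differ
    because the Ct -> reduction map is convex.
    """
    d = np.asarray(delta_cts, dtype=float)
    if d.size == 0:
        raise ValueError("no delta-Ct values")
    if mode == "mean_delta_ct":
        return delta_ct_signal_reduction(float(d.mean()), efficiency)
    if mode == "per_sample":
        return float(
            np.mean([delta_ct_signal_reduction(float(x), efficiency) for x in d])
        )
    raise ValueError("mode must be 'mean_delta_ct' or 'per_sample'")


# ---------------------------------------------------------------------------
# mock community evaluation


@dataclass
class MockSeriesResult:
    ratios: pd.DataFrame
    pearson_r: float
    p_value: float
    methods: tuple[str, str] = field(default=("a", "b"))


def evaluate_mock_series(measured: dict, expected) -> MockSeriesResult:
    """Accuracy and inter-method agreement on a dilution series.

    ``measured`` maps exactly two method names to per-dilution measurements
    on whatever scale that method reports (concentrations, or Ct values --
    the correlation's sign is preserved, so a Ct channel against a
    concentration channel is expected to correlate negatively).  Accuracy
    ratios measured/expected are only meaningful for concentration-scale
    channels; they are reported for all.
    """
    if len(measured) != 2:
        raise ValueError("exactly two methods are required")
    expected = np.asarray(expected, dtype=float)
    if expected.size < 3:
        raise ValueError("at least 3 dilutions are required")
    arrays = {}
    for name, vals in measured.items():
        v = np.asarray(vals, dtype=float)
        if v.shape != expected.shape:
            raise ValueError(f"method {name!r} length mismatch with expected")
        arrays[name] = v
    (name_a, a), (name_b, b) = arrays.items()
    r, p = sps.pearsonr(a, b)
    ratios = pd.DataFrame(
        {name: v / expected for name, v in arrays.items()},
        index=pd.Index(expected, name="expected"),
    )
    return MockSeriesResult(
        ratios=ratios, pearson_r=float(r), p_value=float(p),
        methods=(name_a, name_b),
    )
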
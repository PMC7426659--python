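"""Synthetic fecal-community ground truth and measurement-channel simulation.

The generator emulates a small human cohort profiled in duplicate: each
subject carries a genus-level gut community drawn around one of two
enterotype templates (one *Bacteroides*-dominant, one *Prevotella*-
dominant), a total microbial load in the 10^10 cells/gram range, and an
extracellular/dead-DNA compartment holding a configurable share of the
sample's metagenomic DNA.  Three measurement channels are simulated on top
of the known truth:

* **sequencing** -- multinomial reads with taxon probabilities proportional
  to ``k_t x (intact_t + extracellular_t)`` (untreated libraries) or
  ``k_t x intact_t`` (after propidium-monoazide treatment, which removes
  DNA not protected inside intact cells);
* **cell counting** (flow cytometry) -- the intact-cell load only, with
  multiplicative counting noise;
* **molecular load** (qPCR / ddPCR) -- total 16S copies per gram, distorted
  by a per-aliquot DNA-extraction yield factor (the dominant noise source
  for molecular quantification) and per-taxon technical noise.

All distributions with mean-one multiplicative noise are lognormal with the
requested coefficient of variation; a CV of zero returns the analytic
expectation exactly.  Every operation is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import TaxonCountTable

TREATMENTS = ("untreated", "pma")
MOLECULAR_METHODS = ("qpcr", "ddpcr")

LOAD_COLUMNS = ["sample_id", "replicate", "method", "treatment", "value", "units"]

#: Genus names used for synthetic communities, roughly ordered by typical
#: prevalence in the adult human gut.  Index 0/1 are the two enterotype
#: drivers.
GENUS_NAMES = [
    "Bacteroides", "Prevotella", "Faecalibacterium", "Blautia",
    "Bifidobacterium", "Roseburia", "Ruminococcus", "Alistipes",
    "Akkermansia", "Fusicatenibacter", "Dorea", "Coprococcus",
    "Collinsella", "Parabacteroides", "Dialister", "Oscillibacter",
    "Streptococcus", "Lachnospira", "Eubacterium", "Anaerostipes",
    "Subdoligranulum", "Phascolarctobacterium", "Butyrivibrio",
    "Odoribacter", "Barnesiella", "Paraprevotella", "Sutterella",
    "Desulfovibrio", "Methanobrevibacter", "Christensenella",
    "Veillonella", "Megamonas", "Holdemanella", "Romboutsia",
    "Intestinibacter", "Clostridium", "Flavonifractor", "Butyricimonas",
    "Slackia", "Gordonibacter",
]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults reproduce the emulated study conditions: 16 subjects sampled
    in duplicate, total loads between 1.2e10 and 5.3e10 cells/gram,
    an extracellular compartment holding on average 39% of metagenomic DNA,
    sequencing depths between 153,527 and 282,297 reads, and DNA-extraction
    yield as the dominant molecular-quantification noise source.
    """

    n_subjects: int = 16
    n_replicates: int = 2
    n_taxa: int = 40
    #: fraction of subjects assigned to the *Bacteroides* template
    enterotype_mix: float = 0.5
    load_range: tuple[float, float] = (1.2e10, 5.3e10)
    extracellular_mean: float = 0.39
    #: standard deviation of the per-sample extracellular fraction (Beta);
    #: 0 fixes the fraction at the mean for every sample
    extracellular_sd: float = 0.05
    copy_number_range: tuple[int, int] = (4, 9)
    depth_range: tuple[int, int] = (153_527, 282_297)
    facs_cv: float = 0.05
    extraction_yield_cv: float = 0.5
    qpcr_tech_cv: float = 0.1
    #: Dirichlet concentration of per-subject draws around the templates;
    #: high enough that even tail taxa keep per-taxon shapes well above 1
    #: (tiny shapes would make tail taxa effectively absent at random)
    template_concentration: float = 5000.0
    #: sigma of the per-subject lognormal multiplicative jitter
    subject_lognormal_sigma: float = 0.15
    #: optional per-taxon multipliers biasing the dead/extracellular
    #: compartment toward specific taxa (None = death proportional to
    #: intact abundance, i.e. evenly distributed across taxa)
    death_bias: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_replicates < 1 or self.n_taxa < 1:
            raise ValueError("n_subjects, n_replicates and n_taxa must be >= 1")
        if not 0 <= self.enterotype_mix <= 1:
            raise ValueError("enterotype_mix must be in [0, 1]")
        lo, hi = self.load_range
        if not (0 < lo <= hi):
            raise ValueError("load_range must be a positive interval")
        if not 0 <= self.extracellular_mean < 1:
            raise ValueError("extracellular_mean must be in [0, 1)")
        if self.extracellular_sd < 0:
            raise ValueError("extracellular_sd must be >= 0")
        m = self.extracellular_mean
        if self.extracellular_sd > 0 and self.extracellular_sd ** 2 >= m * (1 - m):
            raise ValueError("extracellular_sd too large for a Beta distribution")
        klo, khi = self.copy_number_range
        if not (1 <= klo <= khi):
            raise ValueError("copy_number_range must be an integer interval >= 1")
        dlo, dhi = self.depth_range
        if not (1 <= dlo <= dhi):
            raise ValueError("depth_range must be an interval with min >= 1")
        for name in ("facs_cv", "extraction_yield_cv", "qpcr_tech_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.death_bias is not None:
            bias = np.asarray(self.death_bias, dtype=float)
            if bias.shape != (self.n_taxa,) or (bias < 0).any():
                raise ValueError("death_bias must be n_taxa non-negative values")


@dataclass
class CommunityTruth:
    """Fully known ground truth for one synthetic cohort.

    ``intact`` holds absolute intact-cell abundances (cells/gram, taxa x
    subjects); ``extracellular`` the extracellular/dead compartment in
    genome-equivalents/gram.  ``loads`` is the per-subject total intact
    load ``L_s = sum_t intact_ts``.  ``extracellular_fraction`` is the
    copy-weighted share of metagenomic DNA held by the extracellular
    compartment, the quantity paired viability-PCR differencing estimates.
    """

    taxa: pd.Index
    copy_numbers: pd.Series
    subjects: pd.Index
    intact: pd.DataFrame
    extracellular: pd.DataFrame
    loads: pd.Series
    enterotype: pd.Series
    moisture: pd.Series
    extracellular_fraction: pd.Series
    config: SimConfig
    seed: int

    def sample_ids(self) -> list[str]:
        """Sequencing-aliquot ids, ``<subject>_r<replicate>``."""
        return [
            f"{s}_r{r}"
            for s in self.subjects
            for r in range(1, self.config.n_replicates + 1)
        ]

    def taxon_dna(self, treatment: str = "untreated") -> pd.DataFrame:
        """Per-taxon 16S copies/gram visible to a molecular assay."""
        _check_treatment(treatment)
        base = self.intact
        if treatment == "untreated":
            base = base + self.extracellular
        return base.mul(self.copy_numbers, axis=0)

    def dna_copies(self, treatment: str = "untreated") -> pd.Series:
        """Total 16S copies/gram per subject."""
        return self.taxon_dna(treatment).sum(axis=0)

    def with_scaled_taxon(
        self, taxon: str, factor: float, subjects: Sequence[str]
    ) -> "CommunityTruth":
        """A modified truth with one taxon's absolute abundance scaled.

        The extracellular compartment of the taxon scales along with the
        intact cells; loads and extracellular fractions are recomputed.
        Useful for constructing paired compositional-effect experiments.
        """
        if factor < 0:
            raise ValueError("factor must be >= 0")
        intact = self.intact.copy()
        extra = self.extracellular.copy()
        intact.loc[taxon, subjects] = intact.loc[taxon, subjects] * factor
        extra.loc[taxon, subjects] = extra.loc[taxon, subjects] * factor
        loads = intact.sum(axis=0)
        k = self.copy_numbers
        total_intact = intact.mul(k, axis=0).sum(axis=0)
        total_extra = extra.mul(k, axis=0).sum(axis=0)
        frac = total_extra / (total_intact + total_extra)
        return dataclasses.replace(
            self,
            intact=intact,
            extracellular=extra,
            loads=loads,
            extracellular_fraction=frac,
        )


def _check_treatment(treatment: str) -> None:
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected {TREATMENTS}")


def _lognormal_mean1(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one lognormal factors with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size)


def _templates(n_taxa: int) -> tuple[np.ndarray, np.ndarray]:
    """Base compositions of the two enterotype templates.

    Abundances decay geometrically (about 1.2x per rank), spanning roughly
    four orders of magnitude over 40 genera -- comparable to genus-level
    fecal profiles -- so adjacent ranks stay resolvable at realistic
    sequencing depths while the tail holds a negligible share of mass.
    """
    ranks = np.arange(n_taxa, dtype=float)
    base = np.exp(-0.20 * ranks)
    bact = base.copy()
    prev = base.copy()
    if n_taxa >= 2:
        bact[0] *= 4.0   # Bacteroides boosted
        bact[1] *= 0.05  # Prevotella suppressed
        prev[1] *= 4.0 * base[0] / base[1]  # Prevotella to Bacteroides-like share
        prev[0] *= 0.3
    return bact / bact.sum(), prev / prev.sum()


def _taxon_names(n_taxa: int) -> list[str]:
    names = list(GENUS_NAMES[:n_taxa])
    while len(names) < n_taxa:
        names.append(f"Genus_{len(names) + 1:02d}")
    return names


def generate_truth(config: SimConfig) -> CommunityTruth:
    """Draw a fully known synthetic cohort from a :class:`SimConfig`.

    Deterministic given ``config.seed``.  Subjects are assigned to one of
    the two enterotype templates, per-subject compositions are Dirichlet
    draws around the template with lognormal multiplicative jitter, loads
    are uniform on the log10 scale within ``load_range``, and higher stool
    moisture monotonically (with noise) thins the number of detectable
    taxa, reproducing the negative moisture-richness association seen in
    fecal cohorts.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_labels, r_copies, r_comp, r_moist, r_loads, r_extra = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    n, t = config.n_subjects, config.n_taxa
    taxa = pd.Index(_taxon_names(t), name="taxon")
    subjects = pd.Index([f"s{i + 1:02d}" for i in range(n)], name="subject")

    # enterotype assignment
    n_bact = int(round(config.enterotype_mix * n))
    order = r_labels.permutation(n)
    labels = np.array(["Prevotella"] * n, dtype=object)
    labels[order[:n_bact]] = "Bacteroides"
    enterotype = pd.Series(labels, index=subjects, name="enterotype")

    copy_numbers = pd.Series(
        r_copies.integers(
            config.copy_number_range[0], config.copy_number_range[1] + 1, t
        ).astype(float),
        index=taxa,
        name="copy_number",
    )

    bact_tpl, prev_tpl = _templates(t)
    comp = np.empty((t, n))
    for j in range(n):
        tpl = bact_tpl if labels[j] == "Bacteroides" else prev_tpl
        theta = (
            r_comp.dirichlet(config.template_concentration * tpl)
            if t > 1
            else np.ones(1)
        )
        jitter = r_comp.lognormal(0.0, config.subject_lognormal_sigma, t)
        v = theta * jitter
        comp[:, j] = v / v.sum()

    # moisture -> richness link: tail taxa drop out independently with a
    # probability that rises with moisture (plus per-subject noise), so
    # richness declines monotonically with moisture without imposing a
    # correlated all-or-nothing presence structure across taxa
    moisture = pd.Series(10.0 + 30.0 * r_moist.beta(2.0, 2.0, n), index=subjects,
                         name="moisture_pct")
    rel = (moisture.to_numpy() - 10.0) / 30.0
    q = np.clip(0.6 * rel + r_moist.normal(0.0, 0.08, n), 0.0, 0.9)
    protected = max(t // 2, 1)
    for j in range(n):
        order_j = np.argsort(comp[:, j])[::-1]
        droppable = order_j[protected:]
        drop = droppable[r_moist.random(len(droppable)) < q[j]]
        comp[drop, j] = 0.0
        comp[:, j] /= comp[:, j].sum()

    log_lo, log_hi = np.log10(config.load_range)
    loads = pd.Series(
        10.0 ** r_loads.uniform(log_lo, log_hi, n), index=subjects, name="load"
    )
    intact = pd.DataFrame(comp * loads.to_numpy(), index=taxa, columns=subjects)

    # extracellular/dead compartment: per-sample DNA fraction f_s, spread
    # across taxa proportionally to intact abundance (optionally biased)
    m, sd = config.extracellular_mean, config.extracellular_sd
    if m == 0:
        frac = np.zeros(n)
    elif sd == 0:
        frac = np.full(n, m)
    else:
        nu = m * (1 - m) / sd ** 2 - 1.0
        frac = r_extra.beta(m * nu, (1 - m) * nu, n)
    bias = (
        np.ones(t)
        if config.death_bias is None
        else np.asarray(config.death_bias, dtype=float)
    )
    k = copy_numbers.to_numpy()
    extra = np.zeros_like(comp)
    for j in range(n):
        w = intact.iloc[:, j].to_numpy() * bias
        kw = float(k @ w)
        if frac[j] > 0 and kw > 0:
            scale = frac[j] / (1.0 - frac[j]) * float(k @ intact.iloc[:, j].to_numpy()) / kw
            extra[:, j] = scale * w
    extracellular = pd.DataFrame(extra, index=taxa, columns=subjects)
    total_i = intact.mul(copy_numbers, axis=0).sum(axis=0)
    total_e = extracellular.mul(copy_numbers, axis=0).sum(axis=0)
    realized_frac = (total_e / (total_i + total_e)).rename("extracellular_fraction")

    return CommunityTruth(
        taxa=taxa,
        copy_numbers=copy_numbers,
        subjects=subjects,
        intact=intact,
        extracellular=extracellular,
        loads=loads,
        enterotype=enterotype,
        moisture=moisture,
        extracellular_fraction=realized_frac,
        config=config,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# measurement channels


def _resolve_depths(truth: CommunityTruth, depth, rng) -> np.ndarray:
    sample_ids = truth.sample_ids()
    if depth is None:
        lo, hi = truth.config.depth_range
        return rng.integers(lo, hi + 1, len(sample_ids))
    if np.isscalar(depth):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        return np.full(len(sample_ids), int(depth))
    if isinstance(depth, (pd.Series, dict)):
        depth = pd.Series(depth).reindex(sample_ids)
        if depth.isna().any():
            raise ValueError("depth mapping missing samples")
        depth = depth.to_numpy()
    depth = np.asarray(depth, dtype=np.int64)
    if depth.shape != (len(sample_ids),):
        raise ValueError("depth vector length must match sample count")
    if (depth < 1).any():
        raise ValueError("depths must be >= 1")
    return depth


def simulate_sequencing(
    truth: CommunityTruth,
    treatment: str = "untreated",
    depth=None,
    seed: int = 0,
) -> TaxonCountTable:
    """Simulate 16S amplicon libraries as multinomial read draws.

    Taxon probabilities are proportional to ``k_t x (intact + extracellular)``
    for untreated libraries and ``k_t x intact`` after PMA treatment.  One
    library per subject x replicate; ``depth`` may be None (drawn uniformly
    from the configured depth range), a scalar, or a per-sample vector /
    mapping.  Column sums equal the requested depths exactly.
    """
    _check_treatment(treatment)
    rng = np.random.default_rng(seed)
    sample_ids = truth.sample_ids()
    depths = _resolve_depths(truth, depth, rng)
    dna = truth.taxon_dna(treatment)
    counts = np.zeros((len(truth.taxa), len(sample_ids)), dtype=np.int64)
    for i, sid in enumerate(sample_ids):
        subject = sid.rsplit("_r", 1)[0]
        w = dna[subject].to_numpy()
        total = w.sum()
        if total <= 0:
            raise ValueError(f"subject {subject} has no DNA to sequence")
        counts[:, i] = rng.multinomial(depths[i], w / total)
    return TaxonCountTable(pd.DataFrame(counts, index=truth.taxa, columns=sample_ids))


def simulate_cell_counts(
    truth: CommunityTruth, facs_cv: float | None = None, seed: int = 0
) -> pd.DataFrame:
    """Flow-cytometry load measurements: intact cells only.

    One measurement per subject x replicate, ``L_s`` times a mean-one
    lognormal counting-noise factor.  The extracellular compartment
    contributes nothing, by the intact-cell contract of cytometry.
    """
    cv = truth.config.facs_cv if facs_cv is None else facs_cv
    if cv < 0:
        raise ValueError("facs_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for subject in truth.subjects:
        for rep in range(1, truth.config.n_replicates + 1):
            noise = _lognormal_mean1(rng, cv, None)
            rows.append(
                (subject, rep, "facs", "untreated",
                 float(truth.loads[subject] * noise), "cells_per_gram")
            )
    return pd.DataFrame(rows, columns=LOAD_COLUMNS)


def _aliquot_ids(truth: CommunityTruth) -> list[tuple[str, int]]:
    return [
        (s, r)
        for s in truth.subjects
        for r in range(1, truth.config.n_replicates + 1)
    ]


def draw_yield_factors(
    truth: CommunityTruth, extraction_yield_cv: float | None = None, seed: int = 0
) -> pd.Series:
    """Per-aliquot DNA-extraction yield factors (mean-one lognormal).

    An aliquot is one subject x replicate; measurements sharing a physical
    aliquot (e.g. a paired untreated/PMA simulation, or qPCR and ddPCR on
    the same extract) should share its yield factor.
    """
    cv = (
        truth.config.extraction_yield_cv
        if extraction_yield_cv is None
        else extraction_yield_cv
    )
    rng = np.random.default_rng(seed)
    ids = [f"{s}_r{r}" for s, r in _aliquot_ids(truth)]
    return pd.Series(_lognormal_mean1(rng, cv, len(ids)), index=ids, name="yield")


def simulate_molecular_load(
    truth: CommunityTruth,
    method: str = "qpcr",
    treatment: str = "untreated",
    extraction_yield_cv: float | None = None,
    tech_cv: float | None = None,
    seed: int = 0,
    yield_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Molecular (qPCR/ddPCR) load measurements in 16S copies/gram.

    ``copies/gram = yield_factor x sum_t k_t x base_t x eps_t`` where
    ``base`` includes the extracellular compartment for untreated aliquots
    only, ``yield_factor`` is drawn per aliquot (or supplied, to share it
    across paired measurements) and ``eps_t`` is per-taxon mean-one
    lognormal technical noise.  qPCR and ddPCR follow the same model with
    independent technical noise streams.
    """
    if method not in MOLECULAR_METHODS:
        raise ValueError(f"unknown method {method!r}; expected {MOLECULAR_METHODS}")
    _check_treatment(treatment)
    ycv = (
        truth.config.extraction_yield_cv
        if extraction_yield_cv is None
        else extraction_yield_cv
    )
    tcv = truth.config.qpcr_tech_cv if tech_cv is None else tech_cv
    rng = np.random.default_rng(seed)
    if yield_factors is None:
        yield_factors = draw_yield_factors(truth, ycv, seed=rng.integers(2 ** 31))
    dna = truth.taxon_dna(treatment)
    rows = []
    for subject, rep in _aliquot_ids(truth):
        aliquot = f"{subject}_r{rep}"
        eps = _lognormal_mean1(rng, tcv, len(truth.taxa))
        total = float(dna[subject].to_numpy() @ eps)
        value = float(yield_factors[aliquot]) * total
        rows.append((subject, rep, method, treatment, value, "copies_per_gram"))
    return pd.DataFrame(rows, columns=LOAD_COLUMNS)


def simulate_paired_molecular_loads(
    truth: CommunityTruth,
    method: str = "qpcr",
    extraction_yield_cv: float | None = None,
    tech_cv: float | None = None,
    seed: int = 0,
    share_technical: bool = False,
) -> pd.DataFrame:
    """Paired untreated/PMA molecular loads sharing per-aliquot yield.

    The extraction-yield factor is drawn once per aliquot and applied to
    both treatments, so it cancels in the paired ratio -- the situation
    viability-PCR differencing relies on.  With ``share_technical=True``
    the per-taxon technical noise is also shared, making the treated
    measurement deterministically <= the untreated one.
    """
    if method not in MOLECULAR_METHODS:
        raise ValueError(f"unknown method {method!r}; expected {MOLECULAR_METHODS}")
    ycv = (
        truth.config.extraction_yield_cv
        if extraction_yield_cv is None
        else extraction_yield_cv
    )
    tcv = truth.config.qpcr_tech_cv if tech_cv is None else tech_cv
    ss = np.random.SeedSequence(seed)
    c_yield, c_unt, c_pma = ss.spawn(3)
    yields = draw_yield_factors(truth, ycv, seed=np.random.default_rng(c_yield).integers(2 ** 31))
    rng_unt = np.random.default_rng(c_unt)
    rng_pma = rng_unt if share_technical else np.random.default_rng(c_pma)

    dna_unt = truth.taxon_dna("untreated")
    dna_pma = truth.taxon_dna("pma")
    rows = []
    for subject, rep in _aliquot_ids(truth):
        aliquot = f"{subject}_r{rep}"
        y = float(yields[aliquot])
        eps_u = _lognormal_mean1(rng_unt, tcv, len(truth.taxa))
        eps_p = eps_u if share_technical else _lognormal_mean1(rng_pma, tcv, len(truth.taxa))
        rows.append(
            (subject, rep, method, "untreated",
             y * float(dna_unt[subject].to_numpy() @ eps_u), "copies_per_gram")
        )
        rows.append(
            (subject, rep, method, "pma",
             y * float(dna_pma[subject].to_numpy() @ eps_p), "copies_per_gram")
        )
    return pd.DataFrame(rows, columns=LOAD_COLUMNS)


# ---------------------------------------------------------------------------
# small conveniences used by the pipeline


def subject_mean_loads(load_table: pd.DataFrame) -> pd.Series:
    """Average replicate measurements into one load per subject."""
    return load_table.groupby("sample_id")["value"].mean()


def loads_for_samples(per_subject: pd.Series, sample_ids: Sequence[str]) -> pd.Series:
    """Broadcast per-subject loads onto ``<subject>_r<rep>`` sample ids."""
    values = {}
    for sid in sample_ids:
        subject = sid.rsplit("_r", 1)[0]
        if subject not in per_subject.index:
            raise KeyError(f"no load for subject {subject}")
        values[sid] = float(per_subject[subject])
    return pd.Series(values)


def aliquot_loads(load_table: pd.DataFrame, treatment: str | None = None) -> pd.Series:
    """Load table rows as a Series indexed by ``<subject>_r<rep>``."""
    df = load_table
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    idx = df["sample_id"].astype(str) + "_r" + df["replicate"].astype(str)
    return pd.Series(df["value"].to_numpy(), index=idx)
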
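"""End-to-end orchestration: simulate, profile, compare, enterotype.

:func:`run_pipeline` chains the stages into the full method-concordance
analysis: synthetic cohort generation (or file input), the four profiling
normalizations, richness, dissimilarity analysis, rank concordance,
extracellular-fraction estimation and DMM enterotyping, writing TSV
artifacts plus a machine-readable JSON summary that embeds the seed and a
hash of the configuration so reruns are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .enterotypes import dmm_assign, fit_dmm, loads_by_cluster_test
from .profiles import CopyNumberTable, qmp_profile, qmp_qpcr_profile, rmp_profile
from .quantify import estimate_extracellular_fraction
from .simulate import (
    SimConfig,
    aliquot_loads,
    generate_truth,
    loads_for_samples,
    simulate_cell_counts,
    simulate_paired_molecular_loads,
    simulate_sequencing,
    subject_mean_loads,
)
from .stats import (
    observed_richness,
    replicate_dissimilarity_analysis,
    top_genus_rank_concordance,
)

log = logging.getLogger(__name__)

ALL_METHODS = ("RMP", "QMP", "QMP-PMA", "QMP-qPCR")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    methods: tuple[str, ...] = ALL_METHODS
    outdir: str | Path = "qmprofiler_out"
    seed: int = 0
    rounding: str = "half_away"
    normalize_bc: bool = False
    k_range: tuple[int, ...] = (1, 2, 3)
    n_starts: int = 3
    dmm_selection: str = "laplace"
    n_top_genera: int = 15

    def validate(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if any(m.startswith("QMP") for m in self.methods):
            pass  # loads are simulated; file-based runs validate in the CLI
        self.sim.validate()

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # where results land does not change them
        if payload["sim"].get("death_bias") is not None:
            payload["sim"]["death_bias"] = list(payload["sim"]["death_bias"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic comparison; returns the result bundle.

    Produces, per requested method, a profile plus richness; across
    methods, the replicate dissimilarity report, top-genus rank
    concordance against RMP, the extracellular-fraction estimate from
    paired qPCR loads, and a two-cluster enterotyping of the relative
    profiles with a load comparison between clusters.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(8)]

    truth = generate_truth(config.sim)
    counts = simulate_sequencing(truth, "untreated", seed=seeds[0])
    counts_pma = simulate_sequencing(truth, "pma", seed=seeds[1])
    cells = simulate_cell_counts(truth, seed=seeds[2])
    facs_loads = subject_mean_loads(cells)
    paired_qpcr = simulate_paired_molecular_loads(truth, "qpcr", seed=seeds[3])
    qpcr_untreated = aliquot_loads(paired_qpcr, "untreated")
    qpcr_pma = aliquot_loads(paired_qpcr, "pma")

    profiles = {}
    if "RMP" in config.methods:
        profiles["RMP"] = rmp_profile(counts, seed=seeds[4])
    if "QMP" in config.methods:
        profiles["QMP"] = qmp_profile(
            counts, truth.copy_numbers,
            loads_for_samples(facs_loads, counts.samples),
            seed=seeds[5], rounding=config.rounding,
        )
    if "QMP-PMA" in config.methods:
        profiles["QMP-PMA"] = qmp_profile(
            counts_pma, truth.copy_numbers,
            loads_for_samples(facs_loads, counts_pma.samples),
            seed=seeds[6], rounding=config.rounding, method_tag="QMP-PMA",
        )
    if "QMP-qPCR" in config.methods:
        profiles["QMP-qPCR"] = qmp_qpcr_profile(
            counts, truth.copy_numbers,
            qpcr_untreated.reindex(counts.samples),
            seed=seeds[7], rounding=config.rounding,
        )

    richness = pd.DataFrame(
        {m: observed_richness(p) for m, p in profiles.items()}
    )
    dissimilarity = (
        replicate_dissimilarity_analysis(profiles, normalize=config.normalize_bc)
        if len(profiles) >= 1
        else None
    )
    concordance = {}
    if "RMP" in profiles:
        for m, p in profiles.items():
            if m == "RMP":
                continue
            concordance[m] = top_genus_rank_concordance(
                profiles["RMP"], p, profiles["RMP"], n_top=config.n_top_genera
            )

    extracellular = estimate_extracellular_fraction(qpcr_untreated, qpcr_pma)

    enterotype_result = None
    if "RMP" in profiles and profiles["RMP"].rarefied is not None:
        model = fit_dmm(
            profiles["RMP"].rarefied, k_range=config.k_range,
            n_starts=config.n_starts, seed=config.seed,
            selection=config.dmm_selection,
        )
        labels = dmm_assign(model)
        load_test = None
        if model.n_components == 2:
            subject_labels = labels.groupby(
                labels.index.map(lambda s: s.rsplit("_r", 1)[0])
            ).first()
            load_test = loads_by_cluster_test(subject_labels, facs_loads)
        enterotype_result = {"model": model, "labels": labels, "load_test": load_test}

    # ------------------------------------------------------------------ write
    qio.write_count_table(counts, outdir / "counts_untreated.tsv")
    qio.write_count_table(counts_pma, outdir / "counts_pma.tsv")
    qio.write_copy_numbers(
        CopyNumberTable(truth.copy_numbers), outdir / "copy_numbers.tsv"
    )
    qio.write_load_table(
        pd.concat([cells, paired_qpcr], ignore_index=True), outdir / "loads.tsv"
    )
    for m, p in profiles.items():
        qio.write_profile(p, outdir / f"profile_{m}.tsv")
    richness.to_csv(outdir / "richness.tsv", sep="\t", index_label="sample_id")
    if dissimilarity is not None:
        dissimilarity.summary.to_csv(
            outdir / "dissimilarity_summary.tsv", sep="\t", index_label="group"
        )
        dissimilarity.tests.to_csv(outdir / "dissimilarity_tests.tsv", sep="\t",
                                   index=False)
    for m, df in concordance.items():
        df.to_csv(outdir / f"concordance_RMP_vs_{m}.tsv", sep="\t")
    if enterotype_result is not None:
        enterotype_result["labels"].to_csv(
            outdir / "enterotype_labels.tsv", sep="\t", index_label="sample_id"
        )
        enterotype_result["model"].selection.to_csv(
            outdir / "enterotype_model_selection.tsv", sep="\t"
        )

    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": config.sim.n_subjects,
        "methods": list(profiles),
        "median_richness": {m: float(richness[m].median()) for m in richness},
        "extracellular_fraction_mean": extracellular.mean_fraction,
        "extracellular_decrease_p": extracellular.p_value,
    }
    if dissimilarity is not None:
        summary["dissimilarity_medians"] = {
            g: float(s.median()) for g, s in dissimilarity.distances.items()
        }
    if enterotype_result is not None:
        summary["enterotype_k"] = enterotype_result["model"].n_components
        if enterotype_result["load_test"] is not None:
            lt = enterotype_result["load_test"]
            summary["enterotype_load_medians"] = {
                str(k): v for k, v in lt.medians.items()
            }
            summary["enterotype_load_p"] = lt.p_value
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    return {
        "truth": truth,
        "counts": counts,
        "counts_pma": counts_pma,
        "profiles": profiles,
        "richness": richness,
        "dissimilarity": dissimilarity,
        "concordance": concordance,
        "extracellular": extracellular,
        "enterotypes": enterotype_result,
        "summary": summary,
    }
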
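"""End-to-end orchestration: inputs -> diversity -> differentiation ->
selection -> supertyping -> report.

``run_pipeline`` reads a single TOML configuration, either simulating a full
dataset from a seed or loading files, executes the stages in dependency
order (skipping stages whose inputs are absent, with a logged warning), and
writes tab-separated tables, a stacked supertype frequency chart, and a
machine-readable ``report.json`` whose content is reproducible under a fixed
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
import tomllib
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import differentiation as diff
from . import io as iom
from . import polymorphism as poly
from . import selection as sel
from . import supertypes as st
from .model import DistanceMatrixLabeled, SiteSelectionTable
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("immunopop")

__all__ = ["run_pipeline", "render_frequency_chart", "load_config"]

DEFAULT_THRESHOLDS = {
    "slac_p": 0.05,
    "rel_bf": 100.0,
    "meme_p": 0.05,
    "min_models": 2,
    "delta_bic": 2.0,
    "variance_retained": 0.95,
}

DEFAULT_RUN = {
    "seed": 1,
    "ci_reps": 10000,
    "mantel_reps": 999,
    "bootstrap_reps": 1000,
    "hwe_reps": 20000,
    "run_sbp": True,
    "k_max": 10,
}


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _matrix_json(matrix: Optional[DistanceMatrixLabeled]):
    if matrix is None:
        return None
    return {
        "labels": matrix.labels,
        "values": [
            [None if math.isnan(v) else v for v in row] for row in matrix.values
        ],
    }


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the full analysis; returns the report dict and writes files."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    run_opts = {**DEFAULT_RUN, **config.get("run", {})}
    seed = int(run_opts["seed"])

    t0 = time.time()
    catalog = dab = msat = geo = None
    selection_tables: list[SiteSelectionTable] = []

    if "simulation" in config:
        sim_kwargs = dict(config["simulation"])
        for key in ("diploids_per_population", "alleles_per_population",
                    "population_names", "coordinates"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in sim_kwargs[key]
                ) if key == "coordinates" else tuple(sim_kwargs[key])
        if "selected_codons" in sim_kwargs:
            sim_kwargs["selected_codons"] = frozenset(sim_kwargs["selected_codons"])
        sim_config = SimulationConfig(**sim_kwargs)
        sim_selected_sites = set(sim_config.selected_codons)
        data = simulate_dataset(sim_config)
        catalog = data["catalog"]
        dab = data["dab_genotypes"]
        msat = data["microsat_genotypes"]
        geo = data["geographic_distances"]
        logger.info("simulation stage done (%.1fs)", time.time() - t0)
    elif "inputs" in config:
        inputs = config["inputs"]
        if "alleles" in inputs:
            catalog = iom.read_allele_fasta(
                inputs["alleles"],
                locus_name=inputs.get("locus", "DAB"),
                codon_mode=True,
            )
        if "genotypes" in inputs:
            dab = iom.read_genotype_table(inputs["genotypes"], catalog=catalog)
        if "microsatellites" in inputs:
            msat = iom.read_genotype_table(inputs["microsatellites"])
        if "coordinates" in inputs:
            geo = iom.read_matrix(inputs["coordinates"])
        for table_path in inputs.get("selection_tables", []):
            selection_tables.append(iom.read_selection_table(table_path))
    else:
        raise ValueError("config needs a [simulation] or [inputs] section")

    if dab is not None and catalog is not None and catalog.locus_name not in dab.loci():
        raise ValueError(
            f"locus {catalog.locus_name!r} absent from genotype table "
            f"(found {dab.loci()})"
        )

    report: dict[str, Any] = {
        "metadata": {
            "seed": seed,
            "config_hash": _config_hash(config),
            "thresholds": thresholds,
        }
    }

    # --- polymorphism -----------------------------------------------------
    if dab is not None and catalog is not None:
        pooled = {}
        for pop in dab.populations:
            for allele, c in dab.allele_counts(pop, catalog.locus_name).items():
                pooled[allele] = pooled.get(allele, 0) + c
        g_dab = 2 * min(
            dab.sample_size(p, catalog.locus_name) for p in dab.populations
        )
        rows = []
        for pop in dab.populations:
            summary = poly.population_summary(
                dab,
                pop,
                [catalog.locus_name],
                catalog=catalog,
                rarefaction_g=g_dab,
                ci_pool=pooled,
                ci_reps=int(run_opts["ci_reps"]),
                seed=seed,
            )
            hwe_p = poly.hwe_exact_test(
                dab.genotype_pairs(pop, catalog.locus_name),
                reps=int(run_opts["hwe_reps"]),
                seed=seed,
            )
            row = dataclasses.asdict(summary)
            row["hwe_p"] = hwe_p
            rows.append(row)
        table1 = pd.DataFrame(rows)
        table1.to_csv(out / "table1.tsv", sep="\t", index=False)
        report["polymorphism"] = table1.to_dict("records")
        logger.info("polymorphism stage done (%.1fs)", time.time() - t0)
    else:
        report["polymorphism"] = None
        logger.warning("polymorphism stage skipped: missing genotypes or alleles")

    # --- richness regression ---------------------------------------------
    report["richness_regression"] = None
    if dab is not None and msat is not None and catalog is not None:
        msat_loci = msat.loci()
        g_msat = 2 * min(
            min(msat.sample_size(p, l) for l in msat_loci)
            for p in msat.populations
        )
        x = []
        y = []
        for pop in dab.populations:
            msat_counts = [msat.allele_counts(pop, l) for l in msat_loci]
            x.append(poly.multilocus_richness(msat_counts, g_msat))
            y.append(
                poly.allelic_richness_rarefaction(
                    dab.allele_counts(pop, catalog.locus_name),
                    2 * min(dab.sample_size(p, catalog.locus_name) for p in dab.populations),
                )
            )
        try:
            reg = poly.richness_regression(x, y)
            report["richness_regression"] = dataclasses.asdict(reg)
        except ValueError as exc:
            logger.warning("richness regression skipped: %s", exc)

    # --- differentiation --------------------------------------------------
    matrices: dict[str, Optional[DistanceMatrixLabeled]] = {
        "allele_d": None,
        "allele_gst_prime": None,
        "microsat_d": None,
        "microsat_gst_prime": None,
        "supertype_d": None,
        "supertype_gst_prime": None,
    }
    if dab is not None and catalog is not None and len(dab.populations) >= 2:
        for stat in ("d", "gst_prime"):
            m = diff.pairwise_differentiation(
                dab, [catalog.locus_name], statistic=stat, estimator="bias_corrected"
            )
            matrices[f"allele_{stat}"] = m
            iom.write_matrix(m, out / f"table3_allele_{stat}.tsv")
    if msat is not None and len(msat.populations) >= 2:
        for stat in ("d", "gst_prime"):
            m = diff.pairwise_differentiation(
                msat, msat.loci(), statistic=stat, estimator="bias_corrected"
            )
            matrices[f"microsat_{stat}"] = m
            iom.write_matrix(m, out / f"table3_microsat_{stat}.tsv")
    logger.info("differentiation stage done (%.1fs)", time.time() - t0)

    # --- selection --------------------------------------------------------
    report["selection"] = None
    supertype_sites: Optional[set[int]] = None
    if catalog is not None and len(catalog) >= 4:
        dnds, z, p_z = sel.codon_z_test(
            catalog, reps=int(run_opts["bootstrap_reps"]), seed=seed
        )
        bp = sel.sbp_scan(catalog) if run_opts["run_sbp"] else None
        slac = sel.slac_sites(catalog, breakpoint=bp)
        internal = SiteSelectionTable(sel.slac_to_selection_rows(slac))
        combined = SiteSelectionTable(
            internal.rows + [r for t in selection_tables for r in t.rows]
        )
        consensus = sel.consensus_selected_sites(
            combined,
            slac_p=thresholds["slac_p"],
            rel_bf=thresholds["rel_bf"],
            meme_p=thresholds["meme_p"],
            min_models=int(thresholds["min_models"]),
        )
        if consensus:
            supertype_sites = consensus
        else:
            supertype_sites = {
                r.site for r in slac if r.p_value < thresholds["slac_p"]
            }
            logger.warning(
                "no multi-model consensus sites; falling back to %d SLAC sites",
                len(supertype_sites),
            )
        if not supertype_sites and "simulation" in config:
            # simulated data: the generator's selected codons are known
            supertype_sites = sim_selected_sites
            logger.warning(
                "no significant sites; supertyping the simulation's %d "
                "selected codons",
                len(supertype_sites),
            )
        iom.write_selection_table(combined, out / "selection_sites.tsv")
        report["selection"] = {
            "z_test": {"dn_minus_ds": dnds, "z": z, "p_one_tailed": p_z},
            "breakpoint": None
            if bp is None
            else {
                "best_position": bp.best_position,
                "delta_aicc": bp.delta_aicc,
                "supported": bp.supported,
            },
            "consensus_sites": sorted(consensus),
            "n_slac_sites": sum(r.p_value < thresholds["slac_p"] for r in slac),
        }
        logger.info("selection stage done (%.1fs)", time.time() - t0)
    else:
        logger.warning("selection stage skipped: fewer than four alleles")

    # --- supertyping ------------------------------------------------------
    report["supertypes"] = None
    if catalog is not None and supertype_sites and len(catalog) >= 2:
        encoding = st.encode_z_descriptors(catalog, supertype_sites)
        model = st.dapc_cluster(
            encoding,
            k_max=min(int(run_opts["k_max"]), len(catalog)),
            variance_retained=thresholds["variance_retained"],
            delta_bic=thresholds["delta_bic"],
            seed=seed,
        )
        pd.DataFrame(
            {"allele_id": list(model.assignments), "supertype": list(model.assignments.values())}
        ).to_csv(out / "supertypes.tsv", sep="\t", index=False)
        report["supertypes"] = {
            "k": model.k,
            "retained_components": model.retained_components,
            "bic_curve": model.bic_curve,
            "sites_used": sorted(supertype_sites),
            "assignments": model.assignments,
        }
        if dab is not None:
            freqs = st.supertype_frequencies(dab, model, locus=catalog.locus_name)
            freqs.frequencies.to_csv(out / "supertype_frequencies.tsv", sep="\t")
            report["supertype_frequencies"] = {
                pop: row.to_dict() for pop, row in freqs.frequencies.iterrows()
            }
            render_frequency_chart(freqs, out / "figure3.svg")
            mapping = model.assignments
            for stat in ("d", "gst_prime"):
                m = diff.pairwise_differentiation(
                    dab,
                    [catalog.locus_name],
                    statistic=stat,
                    estimator="bias_corrected",
                    allele_mapping=mapping,
                )
                matrices[f"supertype_{stat}"] = m
                iom.write_matrix(m, out / f"table3_supertype_{stat}.tsv")
        logger.info("supertyping stage done (%.1fs)", time.time() - t0)
    else:
        logger.warning("supertyping stage skipped: no selected sites available")

    report["differentiation"] = {k: _matrix_json(v) for k, v in matrices.items()}

    # --- isolation by distance -------------------------------------------
    report["mantel"] = None
    if geo is not None:
        mantel_results = {}
        for name, m in matrices.items():
            if m is None or not name.endswith("_d"):
                continue
            aligned = geo.reorder(m.labels) if set(geo.labels) == set(m.labels) else None
            if aligned is None:
                continue
            if np.isnan(m.values).any():
                continue
            r, p = diff.mantel_test(
                m, aligned, reps=int(run_opts["mantel_reps"]), seed=seed
            )
            mantel_results[name] = {"r": r, "p_value": p}
        report["mantel"] = mantel_results
        logger.info("mantel stage done (%.1fs)", time.time() - t0)
    else:
        logger.warning("IBD stage skipped: no coordinates/geographic distances")

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def render_frequency_chart(freq_table: "st.FrequencyTable", path) -> None:
    """Stacked per-population class-frequency bar chart."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freqs = freq_table.frequencies
    if freqs.empty:
        raise ValueError("empty frequency table")
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(freqs), 4))
    bottom = np.zeros(len(freqs))
    for cls in freqs.columns:
        ax.bar(freqs.index, freqs[cls], bottom=bottom, label=cls)
        bottom += freqs[cls].to_numpy()
    ax.set_ylabel("frequency")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
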
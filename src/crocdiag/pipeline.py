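"""End-to-end orchestration: simulate → filter → diagnose-loci → stats →
cluster → hybrid-classify → primer-screen, driven by one YAML config.

Every stage's inputs, outputs and seed are recorded in a JSON manifest with
SHA-256 digests, so a rerun with the same config and seed reproduces
byte-identical CSV outputs.  There is no hidden global state: all
randomness flows from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import pcoa, upgma_newick
from .dart_io import GenotypeMatrix, filter_loci
from .hybrids import DecisionConfig, classify
from .panel import find_diagnostic_loci, hamming_matrix, catt_association, pic_index
from .popgen import amova_two_level, diversity_table, f_statistics
from .primers import screen_panel, synthesize_reference, write_reference
from .simulate import SimConfig, emit_fixture, simulate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "diagnose-loci", "stats", "cluster",
          "hybrid-classify", "primer-screen")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {},            # SimConfig overrides
    "filter": {"min_call_rate": 0.8, "min_reproducibility": 0.0, "depth_tier": 5},
    "panel": {"mode": "fixed_nonfixed", "priority": "A"},
    "stats": {"n_permutations": 99},
    "classify": {},            # DecisionConfig overrides
    "primer": {"flank_len": 60},
}


class ConfigError(ValueError):
    """Configuration failed schema validation (raised before any stage runs)."""


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    cfg = {k: (dict(DEFAULT_CONFIG[k], **raw.get(k, {}))
               if isinstance(DEFAULT_CONFIG[k], dict) else raw.get(k, DEFAULT_CONFIG[k]))
           for k in DEFAULT_CONFIG}
    if cfg["filter"]["depth_tier"] not in (0, 5, 10, 15):
        raise ConfigError("filter.depth_tier must be one of 0, 5, 10, 15")
    try:
        SimConfig(seed=int(cfg["seed"]), **cfg["simulate"]).validate()
        DecisionConfig(**cfg["classify"]).validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config, out_dir: str | Path) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"version": __version__, "seed": seed, "config": cfg,
                      "stages": []}

    def record(stage: str, outputs: dict[str, Path], **extra) -> None:
        manifest["stages"].append({
            "stage": stage,
            "outputs": {k: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                        for k, p in outputs.items()},
            **extra,
        })

    # 1. simulate ----------------------------------------------------------
    sim_cfg = SimConfig(seed=seed, **cfg["simulate"])
    m, truth = simulate_dataset(sim_cfg)
    paths = emit_fixture(m, truth, sim_cfg, out / "simulated")
    record("simulate", paths, n_loci=m.n_loci, n_samples=m.n_samples)

    # 2. filter ------------------------------------------------------------
    fcfg = cfg["filter"]
    filt, report = filter_loci(
        m, min_reproducibility=fcfg["min_reproducibility"],
        min_call_rate=fcfg["min_call_rate"], min_depth=fcfg["depth_tier"],
        return_report=True)
    rep_path = out / "filter_report.csv"
    report.to_frame().to_csv(rep_path, index=False)
    record("filter", {"report": rep_path}, n_retained=filt.n_loci)
    if filt.n_loci == 0:
        logger.warning("filter retained no loci; downstream stages degrade gracefully")

    # 3. diagnose-loci -----------------------------------------------------
    parental = filt.take_samples(
        filt.samples["population"].isin(["CSI", "CPOTH", "CPOAU"]).to_numpy())
    panel = find_diagnostic_loci(parental, mode=cfg["panel"]["mode"],
                                 priority=cfg["panel"]["priority"]) \
        if filt.n_loci else None
    panel_path = out / "panel.csv"
    stats_path = out / "panel_locus_stats.csv"
    if panel is not None and len(panel):
        panel.to_csv(panel_path)
        species_of = parental.samples["population"].map(
            {"CSI": "A", "CPOTH": "B", "CPOAU": "B"})
        rows = []
        for locus in panel.entries.index:
            i = parental.locus_ids.get_loc(locus)
            mc = parental.loci.loc[locus, "marker_class"]
            chi2, p = catt_association(parental.calls[i], species_of.to_numpy(),
                                       scale="genotype", marker_class=mc)
            calls = parental.calls[i]
            called = calls[calls != -1]
            freq = called.sum() / (2 * len(called)) if mc == "snp" and len(called) \
                else (called.mean() if len(called) else np.nan)
            pic = pic_index([1 - freq, freq]) if not np.isnan(freq) else np.nan
            rows.append({"locus_id": locus, "catt_chi2": chi2, "catt_p": p,
                         "pic": pic})
        pd.DataFrame(rows).set_index("locus_id").to_csv(stats_path)
        record("diagnose-loci", {"panel": panel_path, "locus_stats": stats_path},
               n_panel=len(panel),
               n_A=int((panel.entries["species"] == "A").sum()),
               n_B=int((panel.entries["species"] == "B").sum()))
    else:
        logger.warning("diagnostic panel is empty")
        pd.DataFrame(columns=["locus_id", "species", "state", "status",
                              "marker_class"]).to_csv(panel_path, index=False)
        record("diagnose-loci", {"panel": panel_path}, n_panel=0, warning="empty panel")

    # 4. stats -------------------------------------------------------------
    outputs = {}
    if filt.n_loci:
        div = diversity_table(parental)
        outputs["diversity_summary"] = out / "diversity_summary.csv"
        div.to_csv(summary_path=outputs["diversity_summary"])
        fs = f_statistics(parental, n_permutations=cfg["stats"]["n_permutations"],
                          seed=seed + 1)
        outputs["fst_pairwise"] = out / "fst_pairwise.csv"
        fs.fst_pairwise.to_csv(outputs["fst_pairwise"])
        dist_all = hamming_matrix(filt)
        pops = {p: list(g) for p, g in
                parental.samples.groupby("population").groups.items()}
        try:
            am = amova_two_level(dist_all.submatrix(
                [s for ids in pops.values() for s in ids]), pops,
                n_permutations=cfg["stats"]["n_permutations"], seed=seed + 2)
            outputs["amova"] = out / "amova.csv"
            pd.DataFrame([{
                "pct_among": am.pct_among, "pct_within": am.pct_within,
                "phi": am.phi, "p": am.p}]).to_csv(outputs["amova"], index=False)
        except ValueError as exc:
            logger.warning("AMOVA skipped: %s", exc)
        outputs["hamming_long"] = out / "hamming_long.csv"
        dist_all.to_long_csv(outputs["hamming_long"])
        record("stats", outputs, fst_overall=fs.fst_overall)
    else:
        record("stats", {}, warning="no loci after filtering")
        dist_all = None

    # 5. cluster -----------------------------------------------------------
    outputs = {}
    if dist_all is not None and not np.isnan(dist_all.d).any():
        res = pcoa(dist_all)
        outputs["pcoa"] = out / "pcoa_coordinates.csv"
        res.to_csv(outputs["pcoa"])
        outputs["upgma"] = out / "upgma.nwk"
        outputs["upgma"].write_text(upgma_newick(dist_all) + "\n")
        record("cluster", outputs)
    else:
        record("cluster", {}, warning="distance matrix unavailable or incomplete")

    # 6. hybrid-classify ---------------------------------------------------
    if panel is not None and len(panel):
        rep = classify(filt, panel, DecisionConfig(**cfg["classify"]))
        cls_path = out / "hybrid_report.csv"
        rep.to_csv(cls_path)
        txt_path = out / "hybrid_report.txt"
        txt_path.write_text(
            "\n\n".join(rep.text_block(s) for s in rep.table.index) + "\n")
        record("hybrid-classify", {"report": cls_path, "text": txt_path})
    else:
        record("hybrid-classify", {}, warning="empty panel")

    # 7. primer-screen -----------------------------------------------------
    if panel is not None and len(panel):
        reference = synthesize_reference(filt, seed=seed + 3)
        ref_path = out / "synthetic_reference.fasta"
        write_reference(reference, ref_path)
        catalogue = filt.loci.reset_index()[["contig", "position"]]
        screen = screen_panel(filt, panel, reference, snp_catalogue=catalogue,
                              flank_len=cfg["primer"]["flank_len"])
        scr_path = out / "primer_screen.csv"
        screen.to_csv(scr_path)
        record("primer-screen", {"report": scr_path, "reference": ref_path},
               n_pass=int(screen["overall"].sum()))
    else:
        record("primer-screen", {}, warning="empty panel")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
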
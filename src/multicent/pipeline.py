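"""End-to-end orchestration of the hub-detection analysis.

Stages: read edgelist -> giant component -> global statistics -> six
centralities -> max-normalization -> two-round model-based clustering ->
rank-association matrix + index dendrogram -> four-index subset evaluation
-> null-model redundancy suite -> annotation statistics.  Every stage's
output lands in the output directory (TSV for tables, JSON for structured
results, Newick for dendrograms) and a ``report.json`` summarizes the run
with provenance (config hash, seed, package version).

Per-stage seeds are split from the master seed with
``numpy.random.SeedSequence([master_seed, stage_index])`` so any stage can
be re-run independently and the whole run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotstats import (
    chi2_test,
    enrichment_profile,
    ks_two_sample,
    read_annotations,
    solubility_split,
)
from .centrality import centrality_table, write_table
from .graphio import read_edgelist, giant_component, global_stats
from .hubdetect import detect_hubs
from .nullmodels import NullModelSpec, null_redundancy_suite
from .redundancy import association_matrix, evaluate_subset, index_dendrogram

logger = logging.getLogger(__name__)

#: Stage indices used to derive per-stage seeds from the master seed.
_STAGES = ("clustering", "nulls", "subsets")

#: The four-index subsets examined alongside the full six-index profile.
DEFAULT_SUBSETS = (
    ("D", "EC", "TI1", "TI4"),
    ("TI1", "TI4", "B", "C"),
    ("EC", "TI1", "TI4", "B"),
    ("D", "TI1", "TI4", "C"),
)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed (declared derivation rule)."""
    idx = _STAGES.index(stage)
    return int(
        np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2**31)
    )


@dataclass
class PipelineConfig:
    """Run settings; paths are resolved relative to the caller's cwd."""

    edgelist: str
    annotations: str | None = None
    outdir: str = "multicent_out"
    seed: int = 0
    k_min: int = 1
    k_max: int = 20
    n_init: int = 10
    min_central_cluster: int = 10
    central_ratio: float = 0.5
    subsets: Sequence[Sequence[str]] = DEFAULT_SUBSETS
    null_replicates: int = 3
    smallworld_nodes: int | None = None
    smallworld_p: float = 0.05
    run_nulls: bool = True
    run_subsets: bool = True

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


@dataclass
class Report:
    """Summary of a pipeline run; sections are None when skipped."""

    provenance: dict
    stats: dict | None = None
    hubs: dict | None = None
    redundancy: dict | None = None
    subsets: list | None = None
    nulls: dict | None = None
    annotation_tests: dict | None = None
    skipped: dict = field(default_factory=dict)
    error: str | None = None


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute the full analysis; returns the report (also written to disk).

    Stages whose inputs are absent (e.g. no annotation table) are skipped
    with the reason recorded.  A stage failure stops the run but the report
    written so far, plus the error record, still lands in ``outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = Report(
        provenance={
            "config": asdict(config) | {"subsets": [list(s) for s in config.subsets]},
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
        }
    )
    t_start = time.time()
    try:
        _run_stages(config, out, report)
    except Exception as exc:  # noqa: BLE001 - report then re-raise
        report.error = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed: %s", report.error)
        _write_report(report, out)
        raise
    logger.info("pipeline finished in %.1fs", time.time() - t_start)
    _write_report(report, out)
    return report


def _write_report(report: Report, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(asdict(report), indent=2))


def _run_stages(config: PipelineConfig, out: Path, report: Report) -> None:
    t0 = time.time()
    with open(config.edgelist) as fh:
        raw = read_edgelist(fh)
    net = giant_component(raw)
    logger.info(
        "stage read: %d/%d nodes in giant component (%.1fs)",
        net.number_of_nodes(), raw.number_of_nodes(), time.time() - t0,
    )

    t0 = time.time()
    stats = global_stats(net)
    (out / "stats.json").write_text(stats.to_json())
    report.stats = json.loads(stats.to_json())
    logger.info("stage stats done (%.1fs)", time.time() - t0)

    t0 = time.time()
    table = centrality_table(net)
    write_table(table, out / "centrality.tsv")
    logger.info("stage centrality done (%.1fs)", time.time() - t0)

    t0 = time.time()
    hubres = detect_hubs(
        table,
        k_range=(config.k_min, config.k_max),
        n_init=config.n_init,
        seed=stage_seed(config.seed, "clustering"),
        min_central_cluster=config.min_central_cluster,
        central_ratio=config.central_ratio,
    )
    (out / "hubs.json").write_text(hubres.to_json())
    report.hubs = json.loads(hubres.to_json())
    logger.info(
        "stage hubs: %d hubs (%.1fs)", len(hubres.hubs), time.time() - t0
    )

    t0 = time.time()
    assoc = association_matrix(table)
    assoc.to_csv(out / "association.tsv", sep="\t")
    dendro = index_dendrogram(assoc)
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    report.redundancy = {
        "association": json.loads(assoc.to_json(orient="split")),
        "dendrogram_newick": dendro.to_newick(),
        "merge_order": [sorted(m) for m in dendro.merge_order()],
    }
    logger.info("stage redundancy done (%.1fs)", time.time() - t0)

    if config.run_subsets:
        t0 = time.time()
        rows = []
        for subset in config.subsets:
            ev = evaluate_subset(
                table,
                subset,
                hubres.hubs,
                k_range=(config.k_min, config.k_max),
                n_init=config.n_init,
                seed=stage_seed(config.seed, "subsets"),
                min_central_cluster=config.min_central_cluster,
            )
            rows.append(
                {
                    "subset": "-".join(ev.subset),
                    "round1_family": ev.round1.family,
                    "round1_K": ev.round1.n_components,
                    "round1_central_size": ev.round1_central_size,
                    "round2_family": ev.round2.family if ev.round2 else None,
                    "round2_K": ev.round2.n_components if ev.round2 else None,
                    "overlap_1cluster": list(ev.overlap_1cluster),
                    "overlap_2clusters": list(ev.overlap_2clusters),
                    "reference_size": ev.reference_size,
                }
            )
        report.subsets = rows
        (out / "subsets.json").write_text(json.dumps(rows, indent=2))
        logger.info("stage subsets done (%.1fs)", time.time() - t0)
    else:
        report.skipped["subsets"] = "disabled in config"

    if config.run_nulls:
        t0 = time.time()
        nseed = stage_seed(config.seed, "nulls")
        n, m = net.number_of_nodes(), net.number_of_edges()
        sw_nodes = config.smallworld_nodes or max(10, round(n / 2.5))
        sw_k = max(2, 2 * round(m / sw_nodes))
        specs = [
            NullModelSpec(model="gnm", n=n, m=m,
                          replicates=config.null_replicates, seed=nseed),
            NullModelSpec(model="rewired",
                          replicates=config.null_replicates, seed=nseed + 1),
            NullModelSpec(model="smallworld", n=sw_nodes, mean_degree=sw_k,
                          p=config.smallworld_p,
                          replicates=config.null_replicates, seed=nseed + 2),
        ]
        suite = null_redundancy_suite(net, specs)
        nulls = {}
        for name, summary in suite.items():
            summary.mean_matrix.to_csv(out / f"null_{name}.tsv", sep="\t")
            (out / f"null_{name}.nwk").write_text(
                summary.dendrogram.to_newick() + "\n"
            )
            nulls[name] = {
                "manifest": json.loads(summary.manifest()),
                "matrix": json.loads(summary.mean_matrix.to_json(orient="split")),
                "merge_order": [
                    sorted(mg) for mg in summary.dendrogram.merge_order()
                ],
            }
        report.nulls = nulls
        logger.info("stage nulls done (%.1fs)", time.time() - t0)
    else:
        report.skipped["nulls"] = "disabled in config"

    if config.annotations:
        t0 = time.time()
        annot = read_annotations(config.annotations)
        hubs_annot = set(hubres.hubs) & set(annot.index)
        if not hubs_annot:
            report.skipped["annotations"] = (
                "no detected hub appears in the annotation table"
            )
            return
        fat_h, water_h = solubility_split(annot, hubs_annot)
        background = set(annot.index) - hubs_annot
        fat_b, water_b = solubility_split(annot, background)
        contingency = [[fat_h, water_h], [fat_b, water_b]]
        tf_h = int(annot.loc[sorted(hubs_annot), "is_tf"].sum())
        tf_b = int(annot.loc[sorted(background), "is_tf"].sum())
        tf_table = [
            [tf_h, len(hubs_annot) - tf_h],
            [tf_b, len(background) - tf_b],
        ]
        profiles = {
            scheme: enrichment_profile(annot, hubs_annot, scheme)
            for scheme in ("13-class", "6-class")
        }
        ks_profile = {
            scheme: asdict(
                ks_two_sample(
                    prof["subset"].to_numpy(), prof["background"].to_numpy()
                )
            )
            for scheme, prof in profiles.items()
        }
        deg = pd.Series(
            {p: d for p, d in net.degree() if p in annot.index}, dtype=float
        )
        pubs = annot.loc[deg.index, "publications"].astype(float)
        tests = {
            "solubility_contingency": contingency,
            "solubility_chi2": {
                c: asdict(chi2_test(contingency, correction=(c == "yates")))
                for c in ("yates", "uncorrected")
            },
            "tf_contingency": tf_table,
            "tf_chi2": {
                c: asdict(chi2_test(tf_table, correction=(c == "yates")))
                for c in ("yates", "uncorrected")
            },
            "enrichment_profiles": {
                scheme: json.loads(prof.to_json(orient="split"))
                for scheme, prof in profiles.items()
            },
            "profile_ks": ks_profile,
            "degree_vs_publications_ks": asdict(
                ks_two_sample(deg.to_numpy(), pubs.to_numpy())
            ),
        }
        report.annotation_tests = tests
        (out / "annotation_tests.json").write_text(json.dumps(tests, indent=2))
        logger.info("stage annotations done (%.1fs)", time.time() - t0)
    else:
        report.skipped["annotations"] = "no annotation table supplied"
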
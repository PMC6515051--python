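"""End-to-end paranome analysis: CDS FASTA in, WGD report out.

Stages: read/validate sequences -> all-vs-all homology -> families ->
per-pair codon alignment and ML Ks -> node weighting -> 0.1-5 filter ->
mixture fit on ln(Ks) -> candidate-WGD components -> dating under a
substitution rate.  Every intermediate is persisted as TSV/JSON so stages
are individually inspectable and re-runnable; one global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import distribution as dist
from . import families as fam
from . import mixture as mix
from .alignment import align_codon_pair
from .dating import PLANT_AVERAGE_RATE, age_from_ks, wilcoxon_matched
from .ks import estimate_ks
from .sequence_io import SequenceSet, read_cds_fasta, write_validation_report

logger = logging.getLogger("paleoks")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis; the defaults are the canonical
    protocol values (E 1e-5 family / 1e-15 pair, >100 aa, Ks in [0.1, 5],
    0.1 bins, peak window [0.9, 1.5], plant rate 6.1e-9/site/year)."""

    input_fasta: str | None = None
    input_fasta_b: str | None = None  # second dataset: adds Wilcoxon comparison
    out_dir: str = "paleoks_out"
    family_evalue: float = fam.FAMILY_EVALUE
    pair_evalue: float = fam.PAIR_EVALUE
    pair_min_length: int = fam.PAIR_MIN_LENGTH
    min_ks: float = dist.MIN_KS
    max_ks: float = dist.MAX_KS
    bin_width: float = dist.BIN_WIDTH
    peak_window: tuple = dist.PEAK_WINDOW
    rate: float = PLANT_AVERAGE_RATE
    ks_method: str = "ML"
    k_range: tuple = (1, 10)
    n_init: int = 3
    bootstrap: int = 200
    weighting: str = "node"  # or "family" (plain 1/pairs-per-family)
    prefilter: str | None = "kmer"
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        order = ["families", "mixture", "bootstrap"]
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return int(children[order.index(stage)].generate_state(1)[0] % (2**31))


def _analyse_one(seqs: SequenceSet, config: PipelineConfig, out: Path, tag: str) -> dict:
    t0 = time.time()
    write_validation_report(seqs, out / f"{tag}.validation.tsv")

    hits = fam.all_vs_all(
        seqs, family_evalue=config.family_evalue, prefilter=config.prefilter
    )
    fam.write_hits_tsv(hits, out / f"{tag}.hits.tsv")
    families = fam.build_families(
        hits, pair_min_length=config.pair_min_length, pair_evalue=config.pair_evalue
    )
    fam.write_families_tsv(families, out / f"{tag}.families.tsv")
    logger.info("%s: %d hits, %d families (%.1fs)", tag, len(hits), len(families), time.time() - t0)

    # Ks for every within-family pair (node weighting needs the full matrix)
    pair_rows = []
    ks_by_family: dict[str, dict] = {}
    for family in families:
        ks_map = {}
        for a, b in family.all_pairs():
            aln = align_codon_pair(seqs[a], seqs[b])
            est = estimate_ks(aln, method=config.ks_method)
            ks_map[(a, b)] = est.ks if not est.saturated else np.nan
            pair_rows.append(
                [family.family_id, a, b, aln.n_codons, est.ks, est.ka, est.omega,
                 est.t, est.kappa, est.method, est.saturated]
            )
        ks_by_family[family.family_id] = ks_map
    with open(out / f"{tag}.pairs_ks.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["family_id", "id_a", "id_b", "n_codons", "ks", "ka",
                    "omega", "t", "kappa", "method", "saturated"])
        for row in pair_rows:
            w.writerow(row)
    logger.info("%s: %d pair Ks estimates (%.1fs)", tag, len(pair_rows), time.time() - t0)

    # redundancy correction, retention gate, range filter
    weighted = []
    for family in families:
        if config.weighting == "node":
            rows = dist.node_weight(
                family.family_id, family.member_ids, ks_by_family[family.family_id]
            )
        else:
            ks_map = ks_by_family[family.family_id]
            finite = {p: v for p, v in ks_map.items() if np.isfinite(v)}
            rows = [
                dist.WeightedKs(family.family_id, a, b, v, 1.0 / len(finite),
                                f"{family.family_id}.flat")
                for (a, b), v in sorted(finite.items())
            ]
        retained = {h.pair() for h in family.retained_pairs}
        weighted.extend(r for r in rows if tuple(sorted((r.id_a, r.id_b))) in retained)
    filtered = dist.filter_ks(weighted, min_ks=config.min_ks, max_ks=config.max_ks)
    dist.write_weighted_tsv(filtered, out / f"{tag}.weighted_ks.tsv")
    hist = dist.histogram(filtered, bin_width=config.bin_width, max_ks=config.max_ks)
    dist.write_histogram_tsv(hist, out / f"{tag}.histogram.tsv")

    result = {
        "n_sequences": len(seqs),
        "n_rejected": len(seqs.rejected),
        "n_hits": len(hits),
        "n_families": len(families),
        "n_pairs_retained": len(filtered),
        "histogram": hist,
        "pairs": filtered,
    }
    if not filtered:
        logger.warning("%s: no pairs in the Ks window; skipping mixture fit", tag)
        return result

    log_ks = np.log([p.ks for p in filtered])
    wts = np.array([p.weight for p in filtered])
    best, fits = mix.select_k(
        log_ks, weights=wts, k_range=range(config.k_range[0], config.k_range[1] + 1),
        seed=config.stage_seed("mixture"), n_init=config.n_init,
    )
    summaries = mix.summarize_components(
        best, log_ks, weights=wts, B=config.bootstrap, seed=config.stage_seed("bootstrap")
    )
    report = mix.mixture_report(best, summaries)
    report["bic_by_k"] = {f.k: f.bic for f in fits}
    mix.write_mixture_json(report, out / f"{tag}.mixture.json")

    dating = []
    for s in summaries:
        if s.label != "candidate-WGD":
            continue
        res = age_from_ks(s.mean_ks, config.rate)
        lo, hi = (age_from_ks(c, config.rate) for c in s.ci95)
        dating.append(
            {
                "ks_peak": s.mean_ks,
                "rate": config.rate,
                "age_mya": res.age_mya,
                "age_mya_ci95": [lo.age_mya, hi.age_mya],
                "proportion": s.proportion,
            }
        )
    with open(out / f"{tag}.dating.json", "w") as fh:
        json.dump(dating, fh, indent=2)
        fh.write("\n")

    result.update({"mixture": report, "summaries": summaries, "dating": dating})
    _plot(hist, best, out / f"{tag}.ks_distribution.png")
    return result


def _plot(hist, fit, path) -> None:
    """Histogram of weighted Ks with the fitted mixture overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(centers, hist.bin_weights, width=np.diff(hist.bin_edges), color="0.75",
           edgecolor="0.5", linewidth=0.3)
    xs = np.linspace(max(centers[0], 1e-3), centers[-1], 400)
    total = np.zeros_like(xs)
    for m, v, p in zip(fit.means_log, fit.variances_log, fit.proportions):
        # log-normal component density on the Ks axis, scaled to bar mass
        pdf = (
            p / (xs * np.sqrt(2 * np.pi * v))
            * np.exp(-((np.log(xs) - m) ** 2) / (2 * v))
        ) * hist.total_weight * (hist.bin_edges[1] - hist.bin_edges[0])
        ax.plot(xs, pdf, lw=0.8)
        total += pdf
    ax.plot(xs, total, color="red", lw=1.2)
    ax.set_xlabel("Ks")
    ax.set_ylabel("weighted number of duplicate pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, seqs: SequenceSet | None = None,
                 seqs_b: SequenceSet | None = None) -> dict:
    """Run the full analysis; returns the report dict also written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        cfg_dict = asdict(config)
        # stable hash of the settings plus which ones differ from defaults,
        # so a report header always shows whether protocol values were moved
        defaults = asdict(PipelineConfig())
        non_default = sorted(
            k for k, v in cfg_dict.items()
            if k not in ("input_fasta", "input_fasta_b", "out_dir", "seed")
            and v != defaults[k]
        )
        canonical = json.dumps(cfg_dict, sort_keys=True, default=str)
        cfg_dict["config_hash"] = hashlib.md5(canonical.encode()).hexdigest()
        cfg_dict["non_default_settings"] = non_default
        if non_default:
            logger.warning("non-default protocol settings: %s", ", ".join(non_default))
        with open(out / "config.json", "w") as fh:
            json.dump(cfg_dict, fh, indent=2, default=str)
            fh.write("\n")
        if seqs is None:
            if config.input_fasta is None:
                raise ValueError("no input sequences")
            seqs = read_cds_fasta(config.input_fasta)
        report = {"config": cfg_dict, "a": _analyse_one(seqs, config, out, "a")}
        if seqs_b is None and config.input_fasta_b:
            seqs_b = read_cds_fasta(config.input_fasta_b)
        if seqs_b is not None:
            report["b"] = _analyse_one(seqs_b, config, out, "b")
            wres = wilcoxon_matched(
                report["a"]["histogram"].relative_frequencies(),
                report["b"]["histogram"].relative_frequencies(),
            )
            report["comparison"] = {
                "statistic": wres.statistic,
                "p_value": wres.p_value,
                "n_used": wres.n_used,
                "method": wres.method,
            }
            with open(out / "comparison.json", "w") as fh:
                json.dump(report["comparison"], fh, indent=2)
                fh.write("\n")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
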
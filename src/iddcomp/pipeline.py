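"""End-to-end orchestration: extraction, shuffling, similarity, clustering,
motifs and Pfam co-occurrence, with every artifact written as TSV plus a run
manifest. Each stage is re-runnable from the previous stage's outputs; all
randomness is seeded, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .alphabet import AMINO_ACIDS
from .clustering import ClusterProfile, cluster, match_clusters
from .composition import all_vs_all, score_histogram, abundance_histograms
from .io import (
    extract_idd_segments,
    read_fasta,
    read_intervals,
    read_pfam,
    write_fasta,
)
from .motifs import background, log_ratio_histogram, motif_stats, overrepresented
from .pfam import PfamCatalog, cooccurring_pfams, permutation_test
from .randomize import ShuffleSpec, shuffled_counterpart

logger = logging.getLogger(__name__)

_FLOAT = "%.6g"


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the analysis's standard operating point."""

    fasta_a: str
    intervals_a: str
    fasta_b: str
    intervals_b: str
    outdir: str
    pfam_a: str | None = None
    pfam_b: str | None = None
    ordered_fasta: str | None = None
    min_len: int = 30
    w: float = 0.1
    cutoff: float = 0.15
    motif_min: int = 2
    motif_max: int = 5
    min_count: int = 10
    min_cross_ratio: float = 1.25
    n_reps: int = 9000
    shuffle_seed: int = 0
    perm_seed: int = 0
    skip_pfam: bool = False
    per_protein_once: bool = False


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def _hist_frame(edges: np.ndarray, counts: np.ndarray, normalized: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "normalized": normalized,
        }
    )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def _profiles_frame(profiles: list[ClusterProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict = {"cluster_id": p.cluster_id, "size": p.size}
        for i, aa in enumerate(AMINO_ACIDS):
            row[f"mean_{aa}"] = p.mean[i]
        for i, aa in enumerate(AMINO_ACIDS):
            row[f"std_{aa}"] = p.std[i]
        rows.append(row)
    return pd.DataFrame(rows)


def _motif_frame(stats) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif": [s.motif for s in stats],
            "observed": [s.observed for s in stats],
            "expected": [s.expected for s in stats],
            "ratio": [s.ratio if s.ratio is not None else float("nan") for s in stats],
            "ln_ratio": [
                s.log_ratio if s.log_ratio is not None else float("nan") for s in stats
            ],
        }
    )


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "counts": {},
    }
    stage = "load"
    try:
        sets: dict[str, list] = {}
        for label, fa, iv in (
            ("set_a", config.fasta_a, config.intervals_a),
            ("set_b", config.fasta_b, config.intervals_b),
        ):
            stage = f"load:{label}"
            proteins = read_fasta(fa, set_label=label)
            intervals = read_intervals(iv)
            stage = f"extract:{label}"
            segments = extract_idd_segments(proteins, intervals, min_len=config.min_len)
            if not segments:
                raise ValueError("no segments retained by the length filter")
            sets[label] = segments
            manifest["counts"][f"{label}_proteins"] = len(proteins)
            manifest["counts"][f"{label}_segments"] = len(segments)
            write_fasta(segments, out / f"{label}_segments.fasta")
        if config.ordered_fasta:
            stage = "load:ordered"
            sets["ordered"] = read_fasta(config.ordered_fasta, set_label="ordered")
            manifest["counts"]["ordered_sequences"] = len(sets["ordered"])

        stage = "shuffle"
        shuffled: dict[str, list] = {}
        for label, seqs in sets.items():
            shuffled[label] = shuffled_counterpart(
                ShuffleSpec(seed=config.shuffle_seed, source=seqs)
            )
            write_fasta(shuffled[label], out / f"{label}_shuffled.fasta")

        stage = "similarity"
        for label in sets:
            for kind, seqs in (("native", sets[label]), ("shuffled", shuffled[label])):
                m = all_vs_all(seqs, w=config.w)
                h = score_histogram(m)
                _write(
                    _hist_frame(h.bin_edges, h.counts, h.normalized),
                    out / f"{label}_{kind}_similarity_hist.tsv",
                )

        stage = "abundance"
        for label in ("set_a", "set_b"):
            hists = abundance_histograms(sets[label])
            frames = []
            for h in hists:
                df = pd.DataFrame(
                    {
                        "amino_acid": h.amino_acid,
                        "bin_lo": h.bin_edges[:-1],
                        "bin_hi": h.bin_edges[1:],
                        "normalized": h.normalized,
                    }
                )
                frames.append(df)
            _write(pd.concat(frames, ignore_index=True), out / f"{label}_abundance_hist.tsv")

        stage = "cluster"
        clusters: dict[str, list[ClusterProfile]] = {}
        for label in ("set_a", "set_b"):
            profs = cluster(sets[label], cutoff=config.cutoff, w=config.w)
            clusters[label] = profs
            manifest["counts"][f"{label}_clusters"] = len(profs)
            members = pd.DataFrame(
                [
                    {"cluster_id": p.cluster_id, "member_id": mid}
                    for p in profs
                    for mid in p.member_ids
                ]
            )
            _write(members, out / f"{label}_clusters.tsv")
            _write(_profiles_frame(profs), out / f"{label}_cluster_profiles.tsv")

        stage = "match"
        matches = match_clusters(clusters["set_a"], clusters["set_b"], fallback_w=config.w)
        _write(
            pd.DataFrame(
                {
                    "cluster_a": [m.cluster_a for m in matches],
                    "cluster_b": [m.cluster_b for m in matches],
                    "score": [m.score for m in matches],
                }
            ),
            out / "cluster_matches.tsv",
        )

        stage = "motifs"
        stats_by = {}
        for label in sets:
            for kind, seqs in (("native", sets[label]), ("shuffled", shuffled[label])):
                bg = background(seqs)
                for n in range(config.motif_min, config.motif_max + 1):
                    st = motif_stats(seqs, n, bg=bg)
                    stats_by[(label, kind, n)] = st
                    _write(
                        _motif_frame(st), out / f"{label}_{kind}_motifs_n{n}.tsv"
                    )
                    edges, counts = log_ratio_histogram(st, min_count=config.min_count)
                    if edges.size:
                        _write(
                            pd.DataFrame(
                                {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
                            ),
                            out / f"{label}_{kind}_lnratio_hist_n{n}.tsv",
                        )
        for n in range(config.motif_min, config.motif_max + 1):
            rows = overrepresented(
                stats_by[("set_a", "native", n)],
                stats_by[("set_b", "native", n)],
                min_count=config.min_count,
                min_cross_ratio=config.min_cross_ratio,
            )
            _write(
                pd.DataFrame(
                    {
                        "motif": [r.motif for r in rows],
                        "cross_ratio": [
                            f"{r.cross_ratio:.6g}" if r.cross_ratio is not None else "--"
                            for r in rows
                        ],
                        "ratio_a": [f"{r.ratio_a:.6g}" for r in rows],
                        "ratio_b": [
                            f"{r.ratio_b:.6g}" if r.ratio_b is not None else "--"
                            for r in rows
                        ],
                    }
                ),
                out / f"overrepresented_n{n}.tsv",
            )
            manifest["counts"][f"overrepresented_n{n}"] = len(rows)

        if not config.skip_pfam and config.pfam_a and config.pfam_b:
            stage = "pfam"
            cat_a = PfamCatalog.from_pairs(read_pfam(config.pfam_a))
            cat_b = PfamCatalog.from_pairs(read_pfam(config.pfam_b))
            counts_a = cat_a.cluster_counts(
                clusters["set_a"], per_protein_once=config.per_protein_once
            )
            counts_b = cat_b.cluster_counts(
                clusters["set_b"], per_protein_once=config.per_protein_once
            )
            records = cooccurring_pfams(matches, counts_a, counts_b)
            _write(
                pd.DataFrame(
                    {
                        "pfam_id": [r.pfam_id for r in records],
                        "cluster_a": [r.cluster_a for r in records],
                        "count_a": [r.count_a for r in records],
                        "total_a": [r.total_a for r in records],
                        "oe_a": [r.oe_a for r in records],
                        "cluster_b": [r.cluster_b for r in records],
                        "count_b": [r.count_b for r in records],
                        "total_b": [r.total_b for r in records],
                        "oe_b": [r.oe_b for r in records],
                    }
                ),
                out / "pfam_cooccurrence.tsv",
            )
            null = permutation_test(
                matches,
                counts_a,
                counts_b,
                n_reps=config.n_reps,
                seed=config.perm_seed,
            )
            with open(out / "pfam_null_distribution.tsv", "w") as fh:
                fh.write("cooccurrence_count\n")
                for c in null.replicate_counts:
                    fh.write(f"{c}\n")
            manifest["counts"]["cooccurring_pfams"] = null.observed
            manifest["pfam_permutation"] = {
                "observed": null.observed,
                "n_reps": config.n_reps,
                "p_value": null.p_value,
                "null_max": max(null.replicate_counts),
            }
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("pipeline complete: %s", manifest["counts"])
    return manifest
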
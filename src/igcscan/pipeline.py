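"""End-to-end pipeline: ingest -> trees -> quartet tests -> tracks ->
identity scan -> dedup -> rates, with TSV/BED artifacts.

A run is a pure function of (inputs, configuration, seed): every random
draw is seeded from the global seed, and re-running with the same seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .family_io import (
    AlignedFamily,
    PreprocessConfig,
    RejectionReport,
    load_family_table,
    preprocess_alignment,
    read_family_fasta,
    strip_cpg,
)
from .models import IdentityTrackModel, QuartetExcessModel
from .phylo import build_nj_tree, fit_substitution_model, prune_low_support
from .rates import DEFAULT_MU, family_rate
from .tracks_identity import UniqueTrack, deduplicate_tracks
from .tracks_quartet import (
    call_conversion_tracks,
    call_crossover_breakpoints,
    map_call_to_genome,
    partition_topology_blocks,
    select_informative_quartets,
)


@dataclass
class RunConfig:
    """Pipeline configuration (the paper-style defaults: 100 bootstrap
    and simulation replicates, 10,000 permutations, alpha 0.05, bootstrap
    support threshold 0.88)."""

    table: str = ""
    fasta_dir: str = ""
    annotations_dir: str = ""  # optional: *.bed feature files for enrichment
    outdir: str = "igcscan-out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_boot: int = 100
    n_sim: int = 100
    n_perm: int = 10_000
    n_enrich: int = 1000
    alpha: float = 0.05
    support_threshold: float = 0.88
    tree_boot: int = 100
    mu: float = DEFAULT_MU
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pp = PreprocessConfig(**raw.pop("preprocess", {}))
        return cls(preprocess=pp, **raw)


def run_pipeline(cfg: RunConfig, families: list[AlignedFamily] | None = None) -> dict:
    """Execute every stage and write per-stage artifacts to ``cfg.outdir``.

    ``families`` short-circuits ingest (used with synthetic input);
    otherwise families are read from ``cfg.table`` and one aligned FASTA
    per family (``<family_id>.fasta``) in ``cfg.fasta_dir``.
    Returns the run report (also written as ``summary.json``).
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    master = np.random.SeedSequence(cfg.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("tree", "excess", "excess_cpg", "perm", "enrich"), master.spawn(5)
        )
    }
    rejections: list[RejectionReport] = []

    if families is None:
        groups = load_family_table(cfg.table)
        families = []
        for fam_id, members in sorted(groups.items()):
            if len(members) < cfg.preprocess.min_members:
                rejections.append(RejectionReport(fam_id, "min_members",
                                                  f"{len(members)} in table"))
                continue
            raw = read_family_fasta(os.path.join(cfg.fasta_dir, f"{fam_id}.fasta"))
            out = preprocess_alignment(raw, members, cfg.preprocess)
            if isinstance(out, RejectionReport):
                rejections.append(out)
            else:
                families.append(out)

    fam_rows = []
    excess_rows = []
    track_rows = []
    identity_calls = []
    rate_rows = []

    for fam in families:
        tree = build_nj_tree(fam, n_boot=cfg.tree_boot, seed=stage_seeds["tree"])
        pruned = prune_low_support(fam, tree, threshold=cfg.support_threshold,
                                   seed=stage_seeds["tree"], n_boot=cfg.tree_boot)
        if isinstance(pruned, RejectionReport):
            rejections.append(pruned)
            continue
        fam, tree = pruned

        fit = fit_substitution_model(fam, tree)
        res_full = QuartetExcessModel(fam, tree=fit.tree, model=fit.model).fit(
            n_boot=cfg.n_boot, n_sim=cfg.n_sim, seed=stage_seeds["excess"]
        )
        fam_cpg = strip_cpg(fam)
        res_cpg = QuartetExcessModel(fam_cpg, tree=fit.tree, model=fit.model).fit(
            n_boot=cfg.n_boot, n_sim=cfg.n_sim, seed=stage_seeds["excess_cpg"]
        )

        fam_rows.append(
            {
                "family": fam.family_id,
                "n_members": fam.n_members,
                "length": fam.length,
                "mean_identity": round(fam.mean_identity, 6),
            }
        )
        for label, res in (("full", res_full), ("cpg_minus", res_cpg)):
            t = res.test
            excess_rows.append(
                {
                    "family": fam.family_id,
                    "alignment": label,
                    "observed_R": t.observed_R,
                    "ci_R_low": t.ci_R[0],
                    "ci_R_high": t.ci_R[1],
                    "expected_R": round(t.expected_R, 3),
                    "observed_B": t.observed_B,
                    "expected_B": round(t.expected_B, 3),
                    "p_value": t.p_value if t.p_value is not None else "NA",
                    "p_value_B": t.p_value_B if t.p_value_B is not None else "NA",
                    "skipped": t.skipped or "",
                }
            )

        # quartet tracks on the CpG-minus alignment
        exp_b_per_quartet = _expected_b_per_quartet(res_cpg)
        eligible = select_informative_quartets(
            list(zip(res_cpg.test.quartets, exp_b_per_quartet))
        )
        for q in eligible:
            for call in call_conversion_tracks(q, fam.family_id, fam_cpg.length):
                call = map_call_to_genome(call, fam_cpg)
                track_rows.append(_track_row(call, q, fam_cpg))
            for call in call_crossover_breakpoints(q, fam_cpg.length, fam.family_id):
                call = map_call_to_genome(call, fam_cpg)
                track_rows.append(_track_row(call, q, fam_cpg))

        res_ident = IdentityTrackModel(fam).fit(
            n_perm=cfg.n_perm, alpha=cfg.alpha, seed=stage_seeds["perm"]
        )
        identity_calls.extend(res_ident.fragments)

        try:
            est = family_rate(fam.mean_identity, fam.n_members, cfg.mu)
            rate_rows.append(
                {
                    "family": fam.family_id,
                    "n": fam.n_members,
                    "d": round(fam.mean_divergence, 6),
                    "c": est.c,
                    "formula": est.formula_id,
                }
            )
        except ValueError:
            pass

    unique, alignment_only = deduplicate_tracks(identity_calls)

    enrichment_rows = []
    if cfg.annotations_dir and unique and families:
        enrichment_rows = _enrichment_stage(cfg, unique, identity_calls, families)

    _write_tsv(os.path.join(cfg.outdir, "families.tsv"), fam_rows)
    _write_tsv(os.path.join(cfg.outdir, "quartet_excess.tsv"), excess_rows)
    _write_tsv(os.path.join(cfg.outdir, "quartet_tracks.tsv"), track_rows)
    _write_tsv(
        os.path.join(cfg.outdir, "identity_tracks.tsv"),
        [
            {
                "family": f.family_id,
                "seq_a": f.pair[0],
                "seq_b": f.pair[1],
                "aln_start": f.start,
                "aln_stop": f.stop,
                "n_poly_spanned": f.n_poly_spanned,
                "p_global": f.p_global,
                "p_pairwise": f.p_pairwise,
            }
            for f in identity_calls
        ],
    )
    _write_tsv(os.path.join(cfg.outdir, "rates.tsv"), rate_rows)
    if enrichment_rows:
        _write_tsv(os.path.join(cfg.outdir, "enrichment.tsv"), enrichment_rows)
    write_bed_tracks(unique, os.path.join(cfg.outdir, "unique_tracks.bed"))
    if rejections:
        _write_tsv(
            os.path.join(cfg.outdir, "rejections.tsv"),
            [{"family": r.family_id, "reason": r.reason, "detail": r.detail} for r in rejections],
        )

    sig = [r for r in excess_rows if r["alignment"] == "full"
           and r["p_value"] != "NA" and float(r["p_value"]) <= cfg.alpha]
    tested = [r for r in excess_rows if r["alignment"] == "full" and r["p_value"] != "NA"]
    report = {
        "seed": cfg.seed,
        "stage_seeds": stage_seeds,
        "n_families_analyzed": len(fam_rows),
        "n_families_rejected": len(rejections),
        "n_families_tested": len(tested),
        "n_families_significant": len(sig),
        "fraction_significant": len(sig) / len(tested) if tested else None,
        "n_quartet_tracks": len(track_rows),
        "n_identity_calls": len(identity_calls),
        "n_unique_tracks": len(unique),
        "n_enrichment_features": len(enrichment_rows),
        "total_converted_bp": int(sum(t.length for t in unique)),
        "mean_track_length": float(np.mean([t.length for t in unique])) if unique else None,
        "median_track_length": float(np.median([t.length for t in unique])) if unique else None,
        "mean_family_rate": float(np.mean([r["c"] for r in rate_rows])) if rate_rows else None,
    }
    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _enrichment_stage(cfg: RunConfig, unique, identity_calls, families) -> list[dict]:
    """Length-matched re-placement enrichment of the unique track set
    against every BED file in ``cfg.annotations_dir``."""
    import glob

    from .genomic_context import (
        PlacedEvent,
        enrichment_table,
        overlap_features,
        place_random_tracks,
        placement_to_event,
        read_bed,
    )

    annotations = {
        os.path.splitext(os.path.basename(p))[0]: read_bed(p)
        for p in sorted(glob.glob(os.path.join(cfg.annotations_dir, "*.bed")))
    }
    if not annotations:
        return []
    by_id = {f.family_id: f for f in families}
    observed_events = []
    for c in identity_calls:
        if len(c.genome_intervals) != 2:
            continue
        (ca, sa, ea), (cb, sb, eb) = c.genome_intervals.values()
        observed_events.append(PlacedEvent(ca, sa, ea, cb, sb, eb))
    track_lengths = [max(1, t.length) for t in unique]
    usable = [f for f in families if f.length > max(track_lengths)]
    if not observed_events or not usable:
        return []
    null_sets = place_random_tracks(
        track_lengths, usable, n_datasets=cfg.n_enrich,
        seed=int(np.random.SeedSequence([cfg.seed, 4]).generate_state(1)[0] % (2**31)),
    )
    obs_stats = overlap_features(observed_events, annotations)
    null_stats = [
        overlap_features([placement_to_event(p, by_id[p.family_id]) for p in ds],
                         annotations)
        for ds in null_sets
    ]
    return enrichment_table(obs_stats, null_stats).to_dict("records")


def _expected_b_per_quartet(res) -> list[float]:
    """Per-quartet simulation-expected B counts recorded by the test."""
    pqb = res.test.expected_B_per_quartet
    return [] if pqb is None else list(pqb)


def _track_row(call, q, fam: AlignedFamily) -> dict:
    row = {
        "family": call.family_id,
        "quartet": ",".join(call.leaves),
        "kind": call.kind,
        "aln_start": call.start,
        "aln_stop": call.stop,
        "length": call.length,
        "n_R_support": call.n_R_support,
        "alt_topology": call.alt_label,
    }
    for name, (chrom, s, e) in call.genome_intervals.items():
        row[f"genome_{name}"] = f"{chrom}:{s}-{e}"
    return row


def _write_tsv(path, rows: list[dict]) -> None:
    if not rows:
        with open(path, "w") as fh:
            fh.write("")
        return
    cols = list(rows[0])
    for r in rows[1:]:
        for k in r:
            if k not in cols:
                cols.append(k)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)


def write_bed_tracks(tracks: list[UniqueTrack], path) -> int:
    """BED6 of unique tracks: name = family/pair of the best supporting
    call, score = -10*log10(P) capped at 1000.  Returns records written."""
    rows = []
    for t in tracks:
        if not t.chrom:
            continue
        best = t.supporting[0]
        p = t.best_p
        score = 1000 if not np.isfinite(p) or p <= 0 else min(1000, int(round(-10 * np.log10(p))))
        rows.append((t.chrom, t.start, t.end,
                     f"{best.family_id}/{best.pair[0]}~{best.pair[1]}", score, "+"))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return len(rows)


def read_bed_tracks(path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), int(end), name, int(score), strand))
    return out
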
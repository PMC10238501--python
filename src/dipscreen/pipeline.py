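"""End-to-end pipeline: simulate library -> screen -> reads -> map -> stats.

Driven by a structured YAML config; a single global seed is expanded into
independent per-stage streams so each stage is individually reproducible.
Every run writes a machine-readable manifest (config hash, seed, outputs,
headline numbers); reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from . import data as packaged
from .constructs import (
    InsertDesign,
    InsertionEvent,
    TargetConstruct,
    assign_aa_site,
    build_insertion_cds,
    classify_frame,
)
from .mapping import MapParams, build_profile
from .screen import (
    ScreenConfig,
    VariantPhenotype,
    default_schedule,
    light_only_schedule,
    run_screen,
)
from .simulate_reads import (
    LibrarySpec,
    ReadSimSpec,
    pool_from_events,
    sample_library,
    shear_and_read,
    write_fastq,
)
from .stats import (
    cluster_hits,
    coverage_fraction,
    enrichment,
    expected_fraction_observed,
    fold_coverage,
    union_coverage,
)

__all__ = ["PipelineConfig", "load_config", "run_end_to_end"]


@dataclass
class PhenotypeRules:
    """How fusion-level frame calls translate to screen phenotypes.

    Functional in-frame insertions inside the switch window (residue range)
    are photoswitchable; other functional insertions are constitutive.
    Non-functional insertions in the activation-domain repeats retain
    intermediate (truncation-like) activity; all others are dead.
    """

    switch_window: tuple[int, int] = (20, 30)
    activation_domain_start: int = 149
    gfp_high: float = 3000.0
    gfp_intermediate: float = 300.0
    floor: float = 10.0
    noise_cv: float = 0.6


@dataclass
class PipelineConfig:
    target_fasta: str | None = None
    domain_fasta: str | None = None
    tsd_len: int = 5
    variant: str = "LOV02"
    n_clones: int = 2000
    reverse_fraction: float = 0.5
    schedule: str = "default"  # default | light-only
    n_rounds: int = 3
    gate_quantile: float = 0.5
    n_population: int = 100_000
    n_sorted: int = 20_000
    n_reads_per_round: int = 4000
    fragment_len_range: tuple[int, int] = (300, 400)
    read_len: int = 300
    per_base_error: float = 0.001
    rules: PhenotypeRules = field(default_factory=PhenotypeRules)
    out_dir: str = "dipscreen_run"
    seed: int = 0


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    rules = PhenotypeRules(**raw.pop("rules", {}))
    cfg = PipelineConfig(rules=rules, **raw)
    if isinstance(cfg.fragment_len_range, list):
        cfg.fragment_len_range = tuple(cfg.fragment_len_range)
    if isinstance(cfg.rules.switch_window, list):
        cfg.rules.switch_window = tuple(cfg.rules.switch_window)
    return cfg


def _load_target(cfg: PipelineConfig) -> TargetConstruct:
    if cfg.target_fasta is None:
        return packaged.load_gal4_vp64()
    path = Path(cfg.target_fasta)
    if not path.exists():
        raise FileNotFoundError(f"target FASTA not found: {path}")
    rec = next(SeqIO.parse(str(path), "fasta"))
    return TargetConstruct(name=rec.id, cds=str(rec.seq))


def _load_design(cfg: PipelineConfig) -> InsertDesign:
    if cfg.domain_fasta is None:
        return packaged.load_aslov2_design(tsd_len=cfg.tsd_len)
    path = Path(cfg.domain_fasta)
    if not path.exists():
        raise FileNotFoundError(f"domain FASTA not found: {path}")
    rec = next(SeqIO.parse(str(path), "fasta"))
    return InsertDesign(domain_seq=str(rec.seq), tsd_len=cfg.tsd_len)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def assign_phenotype(
    event: InsertionEvent,
    target: TargetConstruct,
    design: InsertDesign,
    rules: PhenotypeRules,
) -> tuple[str, float, float]:
    """(class, gfp_dark, gfp_light) for one insertion event."""
    call = classify_frame(event, design, target)
    if call.functional:
        fusion = build_insertion_cds(target, event, design)
        site = assign_aa_site(fusion, target.protein)
        lo, hi = rules.switch_window
        if lo <= site <= hi:
            return "photoswitchable", rules.gfp_high, rules.floor
        return "constitutive", rules.gfp_high, rules.gfp_high
    if event.p >= 3 * (rules.activation_domain_start - 1):
        return "truncation", rules.gfp_intermediate, rules.gfp_intermediate
    return "dead", rules.floor, rules.floor


def run_end_to_end(cfg: PipelineConfig) -> dict:
    """Run the full pipeline and return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    target = _load_target(cfg)
    design = _load_design(cfg)

    # --- stage 1: transposition library ---------------------------------
    lib = LibrarySpec(
        target=target,
        design=design,
        n_clones=cfg.n_clones,
        reverse_fraction=cfg.reverse_fraction,
        variant=cfg.variant,
    )
    events = sample_library(lib, seeds[0])
    unique: dict[InsertionEvent, int] = {}
    for ev in events:
        unique[ev] = unique.get(ev, 0) + 1
    uniq_events = sorted(unique, key=lambda e: (e.p, e.orientation))
    init_freqs = np.array([unique[e] for e in uniq_events], dtype=float)
    init_freqs /= init_freqs.sum()

    # --- stage 2: phenotypes and FACS screen ----------------------------
    phenos = []
    classes = {}
    for i, ev in enumerate(uniq_events):
        cls, g_dark, g_light = assign_phenotype(ev, target, design, cfg.rules)
        vid = f"p{ev.p}_{ev.orientation[0]}"
        classes[vid] = cls
        phenos.append(
            VariantPhenotype(
                vid, g_dark, g_light, cfg.rules.noise_cv, cfg.rules.floor
            )
        )
    if cfg.schedule == "default":
        gates = default_schedule(cfg.n_rounds, cfg.gate_quantile)
    elif cfg.schedule == "light-only":
        gates = light_only_schedule(cfg.n_rounds, cfg.gate_quantile)
    else:
        raise ValueError(f"unknown schedule preset {cfg.schedule!r}")
    screen_cfg = ScreenConfig(
        phenotypes=phenos,
        frequencies=init_freqs,
        rounds=gates,
        n_population=cfg.n_population,
        n_sorted=cfg.n_sorted,
        seed=seeds[1],
    )
    traj = run_screen(screen_cfg)
    traj.frequencies.to_csv(out / "trajectory_frequencies.tsv", sep="\t")
    traj.gfp_summary.to_csv(out / "trajectory_gfp.tsv", sep="\t")

    # --- stage 3: per-round reads + mapping -----------------------------
    params = MapParams()
    n_sites = target.length - design.tsd_len + 1
    profiles = {}
    round_ids = [0, len(gates)]  # sequence the initial and final libraries
    for rnd in round_ids:
        weights = traj.frequencies.iloc[rnd].to_numpy()
        pool = pool_from_events(uniq_events, target, design, weights=weights)
        pool = [(lab, seq, w) for lab, seq, w in pool if w > 0]
        spec = ReadSimSpec(
            fragment_len_range=cfg.fragment_len_range,
            read_len=cfg.read_len,
            per_base_error=cfg.per_base_error,
            n_reads=cfg.n_reads_per_round,
            seed=seeds[2] + rnd,
        )
        reads = shear_and_read(pool, spec)
        fq = out / f"round{rnd}.fastq"
        write_fastq(reads, fq)
        prof = build_profile(
            fq, target, design, variant=cfg.variant, params=params,
            label=f"round{rnd}",
        )
        prof.to_tsv(out / f"round{rnd}_profile.tsv")
        profiles[rnd] = prof

    # --- stage 4: statistics --------------------------------------------
    first, last = profiles[round_ids[0]], profiles[round_ids[-1]]
    cov = coverage_fraction(first, n_sites)
    fold = fold_coverage(cfg.n_clones, n_sites)
    enr = enrichment(first, last)
    enr.table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # hit clustering over functional forward calls in the final profile
    site_counts: dict[int, int] = {}
    for (p, orient), c in last.counts.items():
        ev = InsertionEvent(p=p, orientation=orient, variant=cfg.variant)
        call = classify_frame(ev, design, target)
        if call.functional:
            fusion = build_insertion_cds(target, ev, design)
            site = assign_aa_site(fusion, target.protein)
            site_counts[site] = site_counts.get(site, 0) + c
    clusters = cluster_hits(site_counts)
    clusters_out = [
        {"sites": cl.sites, "top_site": cl.top_site, "total_count": cl.total_count}
        for cl in clusters
    ]

    manifest = {
        "config": _config_dict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "target": target.name,
        "n_sites": n_sites,
        "library_unique_events": len(uniq_events),
        "fold_coverage": fold,
        "expected_fraction_observed": expected_fraction_observed(fold),
        "observed_coverage_round0": cov,
        "union_coverage_3_libraries": union_coverage(cov, 3),
        "top_variant_final": traj.top_variant(),
        "top_variant_class": classes.get(traj.top_variant(), "unknown"),
        "hit_clusters": clusters_out,
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["fragment_len_range"] = list(cfg.fragment_len_range)
    d["rules"]["switch_window"] = list(cfg.rules.switch_window)
    return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(_config_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
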
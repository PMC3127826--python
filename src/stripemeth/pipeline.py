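"""End-to-end orchestration: simulate or load data, estimate methylation,
summarize bisulfite clones, compute expression ratios, scan features,
write a result bundle.

A single YAML config drives everything; any real-data entry (a FASTA or
Ct table path) overrides its simulation counterpart.  All randomness
flows from one master seed, so a config + seed pair reproduces the bundle
byte for byte.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bisulfite import (AlignerConfig, analyze_clones, compare_stripes,
                        summarize_region)
from .coords import AmpliconFragment, ReferenceRegion
from .expression import expression_table
from .features import count_mcrbc_halfsites, enumerate_mcrbc_pairs, scan_motif
from .io import (config_digest, read_ct_table, read_fasta, write_ct_table,
                 write_fasta, write_results)
from .mcrbc import compare_groups, estimate_table
from .simulate import (gen_bisulfite_clones, gen_molecule_pool, gen_profile,
                       gen_reference, simulate_mcrbc_qpcr)

log = logging.getLogger("stripemeth")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name."""


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError("config must be a YAML mapping")
    return dict(cfg)


def _fragments(entries) -> list[AmpliconFragment]:
    return [AmpliconFragment(int(s), int(e)) for s, e in entries]


def _load_reference(cfg: dict, base: Path, seed: int) -> ReferenceRegion:
    ref_cfg = cfg.get("reference")
    if not ref_cfg:
        raise ConfigError("config needs a 'reference' block")
    if ref_cfg.get("fasta"):
        records = read_fasta(base / ref_cfg["fasta"])
        if not records:
            raise ConfigError(f"no sequences in {ref_cfg['fasta']}")
        name, seq = records[0]
        if "atg_offset" not in ref_cfg:
            raise ConfigError("reference.atg_offset required with reference.fasta")
        return ReferenceRegion(name=name, sequence=seq,
                               atg_offset=int(ref_cfg["atg_offset"]))
    sim = ref_cfg.get("simulate")
    if not sim:
        raise ConfigError("reference block needs either 'fasta' or 'simulate'")
    motifs = [(m, int(p)) for m, p in sim.get("motifs", [])]
    return gen_reference(length=int(sim["length"]),
                         gc_fraction=float(sim.get("gc_fraction", 0.40)),
                         embedded_motifs=motifs, seed=seed,
                         atg_offset=sim.get("atg_offset"))


def run_pipeline(config: dict, outdir: str | Path, base_dir: str | Path = ".") -> dict:
    """Run all configured stages; returns a dict of output paths."""
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir)
    seed = int(config.get("seed", 0))
    root = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0]) for name, s in
                   zip(["reference", "clones", "pool", "qpcr"], root.spawn(4))}
    provenance = {"version": __version__, "config": config_digest(config), "seed": seed}
    outputs: dict[str, Path] = {}
    report: list[str] = []

    def stage(name):
        log.info("stage %s starting (%.1fs elapsed)", name, time.monotonic() - t0)
        return name

    # --- reference -------------------------------------------------------
    name = stage("reference")
    try:
        region = _load_reference(config, base, stage_seeds["reference"])
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {name}: {exc}") from exc
    write_fasta(outdir / "reference.fa", [(region.name, region.sequence)])
    outputs["reference"] = outdir / "reference.fa"
    report.append(f"reference: {region.name}, {len(region)} bp, "
                  f"ATG at index {region.atg_offset}")

    # --- truth profile (simulation only) ---------------------------------
    pair = None
    prof_cfg = config.get("profile")
    if prof_cfg:
        name = stage("profile")
        try:
            pair = gen_profile(
                region,
                base_rates={str(k): float(v) for k, v in prof_cfg["base_rates"].items()},
                blocks=[tuple(b) for b in prof_cfg.get("blocks", [])],
                stripe_delta=float(prof_cfg.get("stripe_delta", 0.0)),
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage {name}: {exc}") from exc
        df = pair.red.to_frame().rename(columns={"p": "p_red"})
        df["p_green"] = pair.green.p
        write_results(outdir / "profile.tsv", df, provenance=provenance)
        outputs["profile"] = outdir / "profile.tsv"

    # --- bisulfite -------------------------------------------------------
    bis_cfg = config.get("bisulfite")
    if bis_cfg:
        name = stage("bisulfite")
        try:
            _run_bisulfite(bis_cfg, region, pair, stage_seeds["clones"], base,
                           outdir, provenance, outputs, report)
        except (ConfigError, StageError):
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage {name}: {exc}") from exc

    # --- mcrbc -----------------------------------------------------------
    mc_cfg = config.get("mcrbc")
    if mc_cfg:
        name = stage("mcrbc")
        try:
            _run_mcrbc(mc_cfg, region, pair, stage_seeds, base, outdir,
                       provenance, outputs, report, config)
        except (ConfigError, StageError):
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage {name}: {exc}") from exc

    # --- expression ------------------------------------------------------
    ex_cfg = config.get("expression")
    if ex_cfg:
        name = stage("expression")
        try:
            table = pd.read_csv(base / ex_cfg["ct_table"], sep="\t", comment="#")
            a, b = ex_cfg.get("compare", ["red", "green"])
            df = expression_table(
                table, ref_gene=ex_cfg.get("ref_gene", "actin"),
                sample_a=str(a), sample_b=str(b),
                efficiencies=ex_cfg.get("efficiencies"),
                default_efficiency=float(ex_cfg.get("efficiency", 2.0)),
            )
            write_results(outdir / "expression.tsv", df, provenance=provenance)
            outputs["expression"] = outdir / "expression.tsv"
            report.append(f"expression: {len(df)} genes, {a} vs {b}")
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage {name}: {exc}") from exc

    # --- features --------------------------------------------------------
    ft_cfg = config.get("features")
    if ft_cfg:
        name = stage("features")
        try:
            _run_features(ft_cfg, region, outdir, provenance, outputs, report)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage {name}: {exc}") from exc

    # --- report ----------------------------------------------------------
    head = " ".join(f"{k}={v}" for k, v in provenance.items())
    text = "\n".join([f"# stripemeth {head}", ""] + report) + "\n"
    (outdir / "report.txt").write_text(text)
    outputs["report"] = outdir / "report.txt"
    log.info("pipeline done in %.1fs", time.monotonic() - t0)
    return outputs


def _run_bisulfite(bis_cfg, region, pair, seed, base, outdir, provenance,
                   outputs, report):
    fragments = _fragments(bis_cfg.get("fragments", []))
    if not fragments:
        raise ConfigError("bisulfite block needs 'fragments'")
    clones_by_sample: dict[str, dict[str, list[tuple[str, str]]]] = {}
    real = bis_cfg.get("clones_fasta")
    if real:
        for sample, path in real.items():
            recs = read_fasta(base / path)
            by_frag = {frag.name: recs for frag in fragments}
            clones_by_sample[str(sample)] = by_frag
    elif pair is not None:
        rng_seed = seed
        n = int(bis_cfg.get("n_clones", 24))
        for k, (sample, profile) in enumerate([("green", pair.green), ("red", pair.red)]):
            by_frag = {}
            for j, frag in enumerate(fragments):
                sim = gen_bisulfite_clones(
                    profile, frag, n,
                    conversion_efficiency=float(bis_cfg.get("conversion_efficiency", 0.995)),
                    seq_error_rate=float(bis_cfg.get("seq_error_rate", 0.001)),
                    seed=rng_seed + 97 * k + j, sample=sample)
                by_frag[frag.name] = sim.clones
                write_fasta(outdir / f"clones_{sample}_{frag.name}.fa", sim.clones)
            clones_by_sample[sample] = by_frag
    else:
        raise ConfigError(
            "bisulfite block needs 'clones_fasta' or a 'profile' block to simulate from")

    cfg = AlignerConfig()
    pos_rows, ctx_rows, clone_rows, cmp_rows = [], [], [], []
    for frag in fragments:
        summaries = {}
        for sample, by_frag in clones_by_sample.items():
            cs = analyze_clones(sample, by_frag[frag.name], region, frag, cfg)
            if cs.n_clones == 0:
                raise StageError(
                    f"stage bisulfite: all clones rejected for {sample}/{frag.name}")
            summ = summarize_region(cs)
            summaries[sample] = summ
            for i, pos in enumerate(summ.atg_positions):
                pos_rows.append({"fragment": frag.name, "sample": sample,
                                 "position": int(pos), "context": summ.contexts[i],
                                 "percent": summ.per_position_percent[i],
                                 "n_calls": int(summ.per_position_calls[i])})
            for ctx, pct in summ.per_context_percent.items():
                ctx_rows.append({"fragment": frag.name, "sample": sample,
                                 "context": ctx, "percent": pct,
                                 "n_calls": summ.per_context_calls[ctx]})
            for cname, pct in zip(summ.clone_names, summ.per_clone_percent):
                clone_rows.append({"fragment": frag.name, "sample": sample,
                                   "clone": cname, "percent": pct})
            report.append(f"bisulfite {frag.name} {sample}: "
                          f"{summ.region_percent:.1f}% over {summ.region_calls} calls")
        if {"green", "red"} <= set(summaries):
            cmp_ = compare_stripes(summaries["green"], summaries["red"])
            cmp_rows.append({"fragment": frag.name,
                             "green_percent": cmp_.green_percent,
                             "red_percent": cmp_.red_percent,
                             "difference": cmp_.region_difference,
                             "fraction_green_higher": cmp_.fraction_green_higher,
                             "n_positions": cmp_.n_positions_compared})
            report.append(f"bisulfite {frag.name} green-red difference: "
                          f"{cmp_.region_difference:.1f} points; "
                          f"{cmp_.fraction_green_higher:.0f}% of positions higher in green")
    write_results(outdir / "bisulfite_per_position.tsv", pos_rows, provenance=provenance)
    write_results(outdir / "bisulfite_per_context.tsv", ctx_rows, provenance=provenance)
    write_results(outdir / "bisulfite_per_clone.tsv", clone_rows, provenance=provenance)
    outputs["bisulfite_per_position"] = outdir / "bisulfite_per_position.tsv"
    outputs["bisulfite_per_context"] = outdir / "bisulfite_per_context.tsv"
    outputs["bisulfite_per_clone"] = outdir / "bisulfite_per_clone.tsv"
    if cmp_rows:
        write_results(outdir / "bisulfite_comparison.tsv", cmp_rows, provenance=provenance)
        outputs["bisulfite_comparison"] = outdir / "bisulfite_comparison.tsv"


def _run_mcrbc(mc_cfg, region, pair, stage_seeds, base, outdir, provenance,
               outputs, report, config):
    efficiency = float(mc_cfg.get("efficiency", 2.0))
    if mc_cfg.get("ct_table"):
        table = read_ct_table(base / mc_cfg["ct_table"])
    else:
        if pair is None:
            raise ConfigError("mcrbc simulation needs a 'profile' block")
        fragments = _fragments(mc_cfg.get("fragments", []))
        if not fragments:
            raise ConfigError("mcrbc block needs 'fragments' (or a ct_table)")
        n_mol = int(mc_cfg.get("n_molecules", 2000))
        tables = []
        for k, (sample, profile) in enumerate([("green", pair.green), ("red", pair.red)]):
            pool = gen_molecule_pool(profile, n_mol, seed=stage_seeds["pool"] + k,
                                     clonal=bool(mc_cfg.get("clonal", True)))
            for j, frag in enumerate(fragments):
                tables.append(simulate_mcrbc_qpcr(
                    pool, region, frag, efficiency=efficiency,
                    ct_at_full_template=float(mc_cfg.get("ct_at_full_template", 24.0)),
                    noise_sd=float(mc_cfg.get("noise_sd", 0.15)),
                    n_replicates=int(mc_cfg.get("n_replicates", 3)),
                    n_digestions=int(mc_cfg.get("n_digestions", 2)),
                    seed=stage_seeds["qpcr"] + 97 * k + j, sample=sample))
        table = pd.concat(tables, ignore_index=True)
        write_ct_table(outdir / "mcrbc_ct.tsv", table, provenance=provenance)
        outputs["mcrbc_ct"] = outdir / "mcrbc_ct.tsv"

    estimates = estimate_table(table, efficiency=efficiency,
                               efficiency_by_fragment=mc_cfg.get("efficiency_by_fragment"))
    rows = [{"sample": e.sample, "fragment": e.fragment,
             "percent": e.percent, "se": e.se,
             "flags": ",".join(sorted(e.flags)) or "-",
             "n_digestions": e.n_digestions, "n_pcr_replicates": e.n_pcr_replicates}
            for e in estimates]
    write_results(outdir / "mcrbc_estimates.tsv", rows, provenance=provenance)
    outputs["mcrbc_estimates"] = outdir / "mcrbc_estimates.tsv"
    for r in rows:
        pct = "withheld" if r["percent"] is None else f"{r['percent']:.1f}%"
        report.append(f"mcrbc {r['fragment']} {r['sample']}: {pct} ({r['flags']})")

    compare = mc_cfg.get("compare") or config.get("compare")
    if compare:
        a, b = (compare.split(":") if isinstance(compare, str) else compare)
        cmp_rows = []
        for frag_name in sorted({e.fragment for e in estimates}):
            va = [e.percent for e in estimates
                  if e.fragment == frag_name and e.sample == a and e.percent is not None]
            vb = [e.percent for e in estimates
                  if e.fragment == frag_name and e.sample == b and e.percent is not None]
            if len(va) >= 2 and len(vb) >= 2:
                res = compare_groups(va, vb)
                cmp_rows.append({"fragment": frag_name, "difference": res.difference,
                                 "t": res.t, "p": res.p,
                                 "significant": "*" if res.significant else ""})
        if cmp_rows:
            write_results(outdir / "mcrbc_comparison.tsv", cmp_rows,
                          provenance=provenance)
            outputs["mcrbc_comparison"] = outdir / "mcrbc_comparison.tsv"


def _run_features(ft_cfg, region, outdir, provenance, outputs, report):
    motif = ft_cfg.get("motif", "CACATG")
    hits = scan_motif(region, motif, both_strands=bool(ft_cfg.get("both_strands", True)))
    span = ft_cfg.get("region")
    if span:
        lo, hi = int(span[0]), int(span[1])
        hits = [h for h in hits if lo <= h.position <= hi]
    write_results(outdir / "features_motifs.tsv",
                  [{"motif": motif, "position": h.position, "strand": h.strand,
                    "match": h.match} for h in hits],
                  columns=["motif", "position", "strand", "match"],
                  provenance=provenance)
    outputs["features_motifs"] = outdir / "features_motifs.tsv"
    sites = count_mcrbc_halfsites(region.sequence,
                                  both_strands=bool(ft_cfg.get("both_strands", True)))
    fwd = [s.position for s in sites if s.strand == "+"]
    pairs = enumerate_mcrbc_pairs(fwd)
    write_results(outdir / "features_halfsites.tsv",
                  [{"n_halfsites": len(sites), "n_forward": len(fwd),
                    "n_eligible_pairs": len(pairs)}],
                  provenance=provenance)
    outputs["features_halfsites"] = outdir / "features_halfsites.tsv"
    report.append(f"features: {len(hits)} {motif} hits"
                  + (f" in {span[0]}..{span[1]}" if span else "")
                  + f"; {len(sites)} half-sites, {len(pairs)} eligible pairs")
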
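"""End-to-end orchestration: forge -> svscan -> depth -> snps -> effects.

``run_all`` executes every stage on a forged mini panel from one YAML
config and one seed, writing a consolidated report directory containing
the five published table shapes (junctions, duplications, identities,
tracts, mutation census) plus a run manifest with the config hash, so a
rerun with the same manifest reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import depth as depth_mod
from . import effects as effects_mod
from . import snps as snps_mod
from . import svscan as svscan_mod
from .annotation import read_gff3
from .catalog import BalancerCatalog
from .forge.reads import SimConfig
from .forge.scenario import STOCK_LABELS, build_mini_world, write_world

log = logging.getLogger("balancerscan")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out": "balancerscan_run",
    "forge": {
        "length": 5_000_000,
        "gene_density": 40.0,
        "depth": 30.0,
        "read_length": 150,
        "insert_mean": 400.0,
        "insert_sd": 40.0,
        "error_rate": 0.0,
        "haplotype_fraction": 0.5,
        "sam_stocks": None,  # null = all stocks
        "aberrations": True,
        "variant_rate_scale": 1.0,
    },
    "svscan": {
        "min_clip": 20, "discord_sds": 3.0, "cluster_radius": 500,
        "min_split_support": 2, "min_discordant_support": 3,
        "min_overlap": 20, "k": 31, "min_block_len": 30,
        "pair_window": 2_000, "match_tol": 100,
        "masked_fraction_max": 0.5, "hamming_tolerant": False,
    },
    "depth": {"window_size": 1000},
    "snps": {"qual_min": 220.0, "min_snps": 10, "max_gap": 100_000,
             "bin": 100_000},
}


@dataclass
class RunConfig:
    seed: int
    out: Path
    forge: dict
    svscan: dict
    depth: dict
    snps: dict
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None,
                  overrides: dict | None = None) -> "RunConfig":
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            for k, v in user.items():
                if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                    cfg[k].update(v)
                else:
                    cfg[k] = v
        for k, v in (overrides or {}).items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            elif v is not None:
                cfg[k] = v
        return cls(seed=int(cfg["seed"]), out=Path(cfg["out"]), forge=cfg["forge"],
                   svscan=cfg["svscan"], depth=cfg["depth"], snps=cfg["snps"], raw=cfg)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


def _sv_config(d: dict) -> svscan_mod.SvConfig:
    return svscan_mod.SvConfig(**{k: v for k, v in d.items()
                                  if k in svscan_mod.SvConfig.__dataclass_fields__})


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the run manifest dict.

    Partial outputs are preserved on failure, with the failing stage
    recorded in the manifest before the exception propagates.
    """
    t0 = time.time()
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}, "config": config.raw}
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s")

    def stage(name):
        log.info("stage=%s status=start", name)
        manifest["stages"][name] = {"status": "running"}

    def done(name, **info):
        manifest["stages"][name] = {"status": "ok", **info}
        log.info("stage=%s status=ok %s", name,
                 " ".join(f"{k}={v}" for k, v in info.items()))

    try:
        # ---------------------------------------------------------- forge
        stage("forge")
        f = config.forge
        world = build_mini_world(length=int(f["length"]), seed=config.seed,
                                 gene_density=float(f["gene_density"]),
                                 with_aberrations=bool(f.get("aberrations", True)),
                                 rate_scale=float(f.get("variant_rate_scale", 1.0)))
        sim = SimConfig(read_length=int(f["read_length"]),
                        insert_mean=float(f["insert_mean"]),
                        insert_sd=float(f["insert_sd"]),
                        depth=float(f["depth"]),
                        error_rate=float(f["error_rate"]),
                        haplotype_fraction=float(f["haplotype_fraction"]),
                        seed=config.seed + 101)
        forge_dir = out / "forge"
        paths = write_world(world, forge_dir, sim, sam_stocks=f.get("sam_stocks"))
        done("forge", n_stocks=len(world.stock_types))

        genome = world.genome.chromosomes
        mask = world.genome.masked_intervals
        catalog = world.catalog
        sv_cfg = _sv_config(config.svscan)

        # --------------------------------------------------------- svscan
        stage("svscan")
        sam_stocks = f.get("sam_stocks")
        stocks_with_sam = sorted(world.stock_types) if sam_stocks is None \
            else list(sam_stocks)
        sv_results = {}
        identities = {}
        for stock in stocks_with_sam:
            res = svscan_mod.scan_sam(paths[f"sam:{stock}"], genome, sv_cfg, mask)
            sv_results[stock] = res
            identities[stock] = svscan_mod.identify_balancer(
                res.aberrations, catalog, tol=sv_cfg.match_tol)
            log.info("stage=svscan stock=%s n_calls=%d identity=%s",
                     stock, len(res.calls), identities[stock])
        _write_junction_table(sv_results, out / "junction_table.tsv")
        _write_identity_table(identities, world, out / "identity_table.tsv")
        done("svscan", stocks=len(sv_results))

        # ---------------------------------------------------------- depth
        stage("depth")
        annotation = read_gff3(paths["annotation"])
        dup_rows = []
        gain_calls_by_stock = {}
        for stock in stocks_with_sam:
            track = depth_mod.window_depth(paths[f"sam:{stock}"],
                                           int(config.depth["window_size"]), mask)
            segs = depth_mod.call_copy_segments(
                depth_mod.segment_track(track),
                junctions=sv_results[stock].calls)
            gains = [s for s in segs if s.label == "gain"]
            gain_calls_by_stock[stock] = gains
            for entry in depth_mod.duplication_report(
                    gains, sv_results[stock].calls, annotation):
                dup_rows.append({"stock": stock, **{k: v for k, v in entry.items()
                                                    if k != "census"},
                                 "census": json.dumps(entry["census"])})
            depth_mod.write_segments_tsv(segs, out / f"depth_segments_{stock}.tsv")
        dup_cols = ["stock", "chrom", "start", "end", "size", "copy_ratio",
                    "bounding_junctions", "census"]
        pd.DataFrame(dup_rows, columns=dup_cols).to_csv(
            out / "duplication_table.tsv", sep="\t", index=False)
        done("depth", n_gain_rows=len(dup_rows))

        # ----------------------------------------------------------- snps
        stage("snps")
        s = config.snps
        vcfs = {stock: paths[f"vcf:{stock}"] for stock in world.stock_types}
        panel = snps_mod.load_panel(vcfs, world.stock_types,
                                    qual_min=float(s["qual_min"]))
        snps_mod.classify_variants(panel)
        all_junctions = [c for r in sv_results.values() for c in r.calls]
        tracts = snps_mod.detect_tracts(panel, int(s["min_snps"]),
                                        int(s["max_gap"]))
        snps_mod.breakpoint_distance(tracts, all_junctions)
        _write_tract_table(tracts, out / "tract_table.tsv")
        snps_mod.class_counts(panel).to_csv(out / "snp_class_counts.tsv",
                                            sep="\t", index=False)
        mat = snps_mod.heatmap_matrix(panel, int(s["bin"]))
        snps_mod.write_heatmap(mat, out / "unique_snp_heatmap.tsv")
        done("snps", n_loci=len(panel.loci), n_tracts=len(tracts))

        # -------------------------------------------------------- effects
        stage("effects")
        effect_calls = []
        for i in panel.loci.index:
            row = panel.loci.loc[i]
            effect_calls.extend(effects_mod.annotate_variant(
                row["chrom"], int(row["pos"]), row["ref"], row["alt"],
                annotation, genome,
                var_id=f"{row['chrom']}:{row['pos']}:{row['ref']}>{row['alt']}"))
        var_classes = {f"{panel.loci.at[i, 'chrom']}:{panel.loci.at[i, 'pos']}:"
                       f"{panel.loci.at[i, 'ref']}>{panel.loci.at[i, 'alt']}":
                       panel.classes.loc[i] for i in panel.loci.index}
        census = effects_mod.census_tables(effect_calls, var_classes)
        census.to_csv(out / "census_table.tsv", sep="\t")
        junction_effects = []
        for stock in stocks_with_sam:
            for c in sv_results[stock].calls:
                junction_effects.extend(
                    effects_mod.annotate_junction(c, annotation))
        pd.DataFrame([e.__dict__ for e in junction_effects]).to_csv(
            out / "junction_effects.tsv", sep="\t", index=False)
        done("effects", n_effect_calls=len(effect_calls))
    except Exception as exc:  # record the failing stage, keep partial outputs
        for name, st in manifest["stages"].items():
            if st.get("status") == "running":
                st.update(status="failed", error=str(exc))
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise

    manifest["elapsed_s"] = round(time.time() - t0, 1)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("run complete in %.1fs", manifest["elapsed_s"])
    return manifest


def _write_junction_table(sv_results: dict, path: Path) -> None:
    rows = []
    for stock, res in sorted(sv_results.items()):
        for ab in res.aberrations:
            for site in ab.sites:
                rows.append({
                    "stock": stock, "aberration_kind": ab.kind,
                    "chrom": site["chrom"],
                    "proximal": site["proximal"], "distal": site["distal"],
                    "delta": site["delta"],
                    "site": site.get("site", "."),
                })
    cols = ["stock", "aberration_kind", "chrom", "proximal", "distal",
            "delta", "site"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def _write_identity_table(identities: dict, world, path: Path) -> None:
    rows = []
    for stock in sorted(world.stock_types):
        label = STOCK_LABELS.get(stock, world.stock_types[stock])
        actual = identities.get(stock, ".")
        rows.append({"stock": stock, "label": label, "actual": actual,
                     "mislabeled": (actual != "." and actual != "unknown"
                                    and actual != label)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_tract_table(tracts: list, path: Path) -> None:
    cols = ["stock", "chrom", "start", "end", "kind", "n_unique_snps",
            "distance_to_nearest_breakpoint"]
    pd.DataFrame([{
        "stock": t.stock, "chrom": t.chrom, "start": t.start, "end": t.end,
        "kind": t.kind, "n_unique_snps": t.n_unique_snps,
        "distance_to_nearest_breakpoint":
            t.distance_to_nearest_breakpoint
            if t.distance_to_nearest_breakpoint is not None else "NA",
    } for t in tracts], columns=cols).to_csv(path, sep="\t", index=False)
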
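"""Panel-wide SNP sharing classes, crossover tracts and breakpoint distances.

Per-stock VCFs (each stock sequenced as a balancer/reference heterozygote)
are merged positionally into a stocks x loci presence matrix. Loci passing
the quality filter are classified set-theoretically:

* ``shared_all``    — present in every stock of at least two balancer types
* ``type_specific`` — present in all stocks of exactly one type and absent
                      from all stocks of other types
* ``stock_unique``  — present in exactly one stock
* ``other``         — any remaining passing locus

Runs of stock-unique loci betray recombination with a non-balancer homolog:
a run abutting a chromosome end is a single crossover (SCO), an interior
run a double crossover (DCO).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

QUAL_MIN_DEFAULT = 220.0


@dataclass
class PanelMatrix:
    stocks: list[str]
    stock_types: dict[str, str]
    loci: pd.DataFrame      # chrom,pos,ref,alt,var_class,qual_max columns, one row/locus
    presence: pd.DataFrame  # bool, index aligned with loci rows, columns = stocks
    contig_lengths: dict[str, int] = field(default_factory=dict)
    classes: pd.Series | None = None

    def passing(self, qual_min: float = QUAL_MIN_DEFAULT) -> np.ndarray:
        return (self.loci["qual_max"] > qual_min).to_numpy()


def load_panel(vcfs: dict[str, str | Path], stock_types: dict[str, str],
               qual_min: float = QUAL_MIN_DEFAULT) -> PanelMatrix:
    """Merge per-stock VCFs positionally into a presence matrix.

    Loci with QUAL <= ``qual_min`` in every stock are dropped; multiallelic
    records are split; indels are retained but flagged by ``var_class``.
    Presence means any non-reference genotype call at the locus.
    """
    stocks = sorted(vcfs)
    records: dict[tuple, dict] = {}
    contigs: dict[str, int] | None = None
    for stock in stocks:
        vf = pysam.VariantFile(str(vcfs[stock]))
        lens = {c: vf.header.contigs[c].length for c in vf.header.contigs}
        if contigs is None:
            contigs = lens
        elif set(lens) != set(contigs) or any(contigs[c] != lens[c] for c in lens):
            raise ValueError(f"{stock}: VCF contigs disagree with the rest of the panel")
        for rec in vf:
            for alt in rec.alts or ():
                key = (rec.chrom, rec.pos, rec.ref, alt)
                entry = records.setdefault(key, {"qual": 0.0, "stocks": set()})
                entry["qual"] = max(entry["qual"], rec.qual or 0.0)
                present = True
                if rec.samples:
                    gts = [rec.samples[s]["GT"] for s in rec.samples]
                    present = any(g and any(a not in (0, None) for a in g) for g in gts)
                if present:
                    entry["stocks"].add(stock)
    keys = sorted(records)
    keep = [k for k in keys if records[k]["qual"] > qual_min]
    loci = pd.DataFrame([{
        "chrom": c, "pos": p, "ref": r, "alt": a,
        "var_class": ("snp" if len(r) == 1 and len(a) == 1
                      else "ins" if len(a) > len(r) else "del"),
        "qual_max": records[(c, p, r, a)]["qual"],
    } for c, p, r, a in keep],
        columns=["chrom", "pos", "ref", "alt", "var_class", "qual_max"])
    presence = pd.DataFrame(
        {s: [s in records[k]["stocks"] for k in keep] for s in stocks},
        index=loci.index if len(loci) else None, dtype=bool)
    if len(loci) == 0:
        presence = pd.DataFrame(columns=stocks, dtype=bool)
    return PanelMatrix(stocks, dict(stock_types), loci, presence, contigs or {})


def classify_variants(panel: PanelMatrix) -> PanelMatrix:
    """Assign exactly one sharing class to every passing locus (in place).

    Also stores both shared-variant counts on the panel: the operational
    "present in every stock of >= 2 types" definition used for the class,
    and the strict all-types intersection.
    """
    types = sorted(set(panel.stock_types.values()))
    by_type = {t: [s for s in panel.stocks if panel.stock_types[s] == t] for t in types}
    pres = panel.presence.to_numpy()
    cols = {s: i for i, s in enumerate(panel.stocks)}
    classes = []
    n_shared_strict = 0
    for i in range(len(panel.loci)):
        row = pres[i]
        n_present = int(row.sum())
        full_types = [t for t in types if all(row[cols[s]] for s in by_type[t])]
        any_types = {panel.stock_types[s] for s in panel.stocks if row[cols[s]]}
        if len(full_types) >= 2:
            classes.append("shared_all")
            if len(full_types) == len(types):
                n_shared_strict += 1
        elif n_present == 1:
            stock = [s for s in panel.stocks if row[cols[s]]][0]
            classes.append(f"stock_unique:{stock}")
        elif len(full_types) == 1 and any_types == {full_types[0]}:
            classes.append(f"type_specific:{full_types[0]}")
        else:
            classes.append("other")
    panel.classes = pd.Series(classes, index=panel.loci.index, dtype=object)
    panel.n_shared_operational = sum(c == "shared_all" for c in classes)
    panel.n_shared_strict = n_shared_strict
    return panel


def class_counts(panel: PanelMatrix) -> pd.DataFrame:
    """Tabulate loci per sharing class (passing loci only)."""
    if panel.classes is None:
        raise ValueError("run classify_variants first")
    grouped = panel.classes.map(lambda c: c.split(":")[0]).value_counts()
    return grouped.rename_axis("class").reset_index(name="n_loci")


@dataclass
class TractCall:
    stock: str
    chrom: str
    start: int  # boundary interval outer edges, 1-based
    end: int
    inner_start: int  # outermost unique loci of the run
    inner_end: int
    kind: str  # SCO | DCO
    n_unique_snps: int
    distance_to_nearest_breakpoint: int | None = None


def detect_tracts(panel: PanelMatrix, min_snps: int = 10, max_gap: int = 100_000) -> list[TractCall]:
    """Maximal runs of stock-unique loci as crossover tract calls.

    A tract is a run of >= ``min_snps`` stock-unique loci for one stock with
    inter-locus gaps <= ``max_gap``; it is an SCO when an outermost locus
    lies within ``max_gap`` of a chromosome end, a DCO otherwise. Boundaries
    are the interval between the outermost unique locus and the nearest
    flanking informative locus — a non-unique locus the stock actually
    carries, i.e. evidence it still holds balancer-shared sequence there
    (inside an exchanged tract the stock also lacks the shared variants) —
    or the chromosome end.
    """
    if panel.classes is None:
        raise ValueError("run classify_variants first")
    out: list[TractCall] = []
    loci = panel.loci
    for stock in panel.stocks:
        tag = f"stock_unique:{stock}"
        for chrom, grp in loci.groupby("chrom", sort=True):
            cls = panel.classes.loc[grp.index]
            sel = grp.index[cls == tag]
            positions = grp.loc[sel, "pos"].sort_values().to_numpy()
            carried = panel.presence.loc[grp.index, stock].to_numpy()
            informative = np.sort(
                grp.loc[(cls != tag).to_numpy() & carried, "pos"].to_numpy())
            if len(positions) == 0:
                continue
            clen = panel.contig_lengths.get(chrom)
            runs = np.split(positions, np.flatnonzero(np.diff(positions) > max_gap) + 1)
            for run in runs:
                if len(run) < min_snps:
                    continue
                lo, hi = int(run[0]), int(run[-1])
                left_inf = informative[informative < lo]
                right_inf = informative[informative > hi]
                start = int(left_inf[-1]) + 1 if len(left_inf) else 1
                end = int(right_inf[0]) - 1 if len(right_inf) else (clen or hi)
                near_edge = lo <= max_gap or (clen is not None and clen - hi <= max_gap)
                kind = "SCO" if near_edge else "DCO"
                out.append(TractCall(stock, chrom, start, end, lo, hi, kind, len(run)))
    out.sort(key=lambda t: (t.stock, t.chrom, t.start))
    return out


def ancestral_compare(panel: PanelMatrix, target_stock: str, ancestor_stock: str,
                      min_snps: int = 10, max_gap: int = 100_000) -> list[TractCall]:
    """Runs of loci where a stock differs from an ancestral snapshot.

    Comparing each stock against a chromosome assumed to carry the lineage's
    ancestral polymorphism profile reveals which stocks experienced
    crossovers; a stock with no qualifying run has the ancestral profile.
    """
    if target_stock not in panel.presence.columns:
        raise ValueError(f"unknown stock {target_stock!r}")
    anc = panel.presence[ancestor_stock]
    if not anc.any():
        raise ValueError("ancestor column is empty; cannot define a snapshot")
    diff = panel.presence[target_stock] != anc
    out = []
    for chrom, grp in panel.loci.groupby("chrom", sort=True):
        positions = grp.loc[diff.loc[grp.index], "pos"].sort_values().to_numpy()
        informative = np.sort(grp.loc[~diff.loc[grp.index], "pos"].to_numpy())
        if len(positions) == 0:
            continue
        clen = panel.contig_lengths.get(chrom)
        runs = np.split(positions, np.flatnonzero(np.diff(positions) > max_gap) + 1)
        for run in runs:
            if len(run) < min_snps:
                continue
            lo, hi = int(run[0]), int(run[-1])
            left_inf = informative[informative < lo]
            right_inf = informative[informative > hi]
            start = int(left_inf[-1]) + 1 if len(left_inf) else 1
            end = int(right_inf[0]) - 1 if len(right_inf) else (clen or hi)
            near_edge = lo <= max_gap or (clen is not None and clen - hi <= max_gap)
            out.append(TractCall(target_stock, chrom, start, end, lo, hi,
                                 "SCO" if near_edge else "DCO", len(run)))
    return out


def breakpoint_distance(tracts: list[TractCall], junctions: list) -> list[TractCall]:
    """Annotate each tract with the distance to the nearest junction flank.

    With no junctions the distance stays None (undefined, not zero).
    """
    flanks = []
    for j in junctions or []:
        for chrom, pos, _ in (j.flank_a, j.flank_b):
            flanks.append((chrom, pos))
    for t in tracts:
        ds = [min(abs(t.inner_start - p), abs(t.inner_end - p))
              for c, p in flanks if c == t.chrom]
        t.distance_to_nearest_breakpoint = min(ds) if ds else None
    return tracts


def heatmap_matrix(panel: PanelMatrix, bin_size: int = 100_000) -> pd.DataFrame:
    """Stocks x genomic-bin counts of stock-unique loci.

    Rows are stocks; columns are (chrom, bin start). Mirrors the unique-SNP
    heatmaps used to visualize sequence diversity along each balancer.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if panel.classes is None:
        raise ValueError("run classify_variants first")
    cols = []
    for chrom in sorted(panel.contig_lengths):
        L = panel.contig_lengths[chrom] or int(
            panel.loci.loc[panel.loci["chrom"] == chrom, "pos"].max() or 0)
        cols.extend((chrom, b * bin_size + 1) for b in range(-(-L // bin_size)))
    mat = pd.DataFrame(0, index=panel.stocks,
                       columns=pd.MultiIndex.from_tuples(cols, names=["chrom", "bin_start"])
                       if cols else [], dtype=int)
    for i in panel.loci.index:
        cls = panel.classes.loc[i]
        if not cls.startswith("stock_unique:"):
            continue
        stock = cls.split(":", 1)[1]
        chrom = panel.loci.at[i, "chrom"]
        b = (int(panel.loci.at[i, "pos"]) - 1) // bin_size * bin_size + 1
        if (chrom, b) in mat.columns:
            mat.loc[stock, (chrom, b)] += 1
    return mat


def write_heatmap(mat: pd.DataFrame, tsv_path: str | Path,
                  png_path: str | Path | None = None) -> None:
    mat.to_csv(tsv_path, sep="\t")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 0.5 * max(2, len(mat.index))))
        if mat.size:
            ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
            ax.set_yticks(range(len(mat.index)), mat.index)
        ax.set_xlabel("genomic bin")
        fig.savefig(png_path, dpi=100, bbox_inches="tight")
        plt.close(fig)
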
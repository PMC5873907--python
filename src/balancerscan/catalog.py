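"""Balancer catalogs: known component aberrations and their breakpoints.

A catalog maps each balancer to the component aberrations it must carry
(e.g. SM6a carries In(2L)Cy, In(2R)Cy, In(2LR)SM1 and In(2LR)O), and each
aberration to its breakpoint sites. The package ships the published second
chromosome catalog (dm6 coordinates) as data; the synthetic forge emits an
analogous catalog for its planted mini worlds.

Breakpoint coordinates follow the retained-flank convention: each site row
prints the junction-adjacent retained base of each product. The signed
junction delta is recomputed from a site's printed flanks as

    s = distal - proximal   (head site: the aberration's first breakpoint)
    s = proximal - distal   (tail site: the second breakpoint)

    delta = s        if s > 0   (s bases duplicated, present on both sides)
            0        if s = 0   (blunt junction)
            -(|s|-1) if s < 0   (bases strictly between the flanks deleted)

Two published rows (+4 and +2 on In(2L)SM5-1) are internally inconsistent
with this convention by one base; they are flagged rather than matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd


def delta_from_flanks(proximal: int, distal: int, site: str = "head") -> int:
    """Signed junction delta from printed retained-flank coordinates."""
    if site not in ("head", "tail"):
        raise ValueError("site must be 'head' or 'tail'")
    s = distal - proximal if site == "head" else proximal - distal
    if s > 0:
        return s
    if s == 0:
        return 0
    return -(-s - 1)


@dataclass(frozen=True)
class BreakpointSite:
    aberration: str
    polytene: str
    site: str  # head | tail
    chrom: str
    proximal: int | None
    distal: int | None
    printed_delta: int | None
    predicted_band: str = "."
    disrupts: str = "."

    @property
    def known(self) -> bool:
        return self.proximal is not None and self.distal is not None

    def recomputed_delta(self) -> int | None:
        if not self.known:
            return None
        return delta_from_flanks(self.proximal, self.distal, self.site)


@dataclass
class BalancerCatalog:
    """balancer -> required aberration names, plus per-aberration sites."""

    balancers: dict[str, list[str]]
    sites: dict[str, list[BreakpointSite]] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for name, abs_ in self.balancers.items():
            key = frozenset(abs_)
            if key in seen:
                raise ValueError(f"catalog entry {name} duplicates another balancer's "
                                 "aberration set")
            seen.add(key)

    def matchable_sites(self, aberration: str) -> list[BreakpointSite]:
        return [s for s in self.sites.get(aberration, []) if s.known]

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "BalancerCatalog":
        """Load a catalog; defaults to the packaged published 2nd-chromosome one."""
        if path is None:
            path = resources.files("balancerscan.data") / "balancer_breakpoints.tsv"
        df = pd.read_csv(path, sep="\t", dtype=str)
        sites: dict[str, list[BreakpointSite]] = {}
        balancers: dict[str, set] = {}
        for _, row in df.iterrows():
            def _int(x):
                return None if pd.isna(x) or x == "NA" else int(x)
            site = BreakpointSite(
                aberration=row["aberration"], polytene=row["polytene"],
                site=row["site"], chrom=row["chrom"],
                proximal=_int(row["proximal"]), distal=_int(row["distal"]),
                printed_delta=_int(row["printed_delta"]),
                predicted_band=row.get("predicted_band", "."),
                disrupts=row.get("disrupts", "."),
            )
            sites.setdefault(row["aberration"], []).append(site)
            for b in row["balancers"].split(","):
                balancers.setdefault(b.strip(), set()).add(row["aberration"])
        return cls({b: sorted(a) for b, a in balancers.items()}, sites)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        inv = {}
        for b, abs_ in self.balancers.items():
            for a in abs_:
                inv.setdefault(a, []).append(b)
        for ab, ss in self.sites.items():
            for s in ss:
                rows.append({
                    "balancers": ",".join(sorted(inv.get(ab, []))),
                    "aberration": ab, "polytene": s.polytene, "site": s.site,
                    "chrom": s.chrom,
                    "proximal": s.proximal if s.proximal is not None else "NA",
                    "distal": s.distal if s.distal is not None else "NA",
                    "printed_delta": s.printed_delta if s.printed_delta is not None else "NA",
                    "predicted_band": s.predicted_band, "disrupts": s.disrupts,
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def check_breakpoint_deltas(catalog: BalancerCatalog | None = None) -> pd.DataFrame:
    """Recompute every known site's delta from its printed flanks.

    Returns one row per coordinate-resolved site with the printed delta, the
    recomputed delta, and whether they agree; disagreeing rows are the
    published one-base-inconsistent entries.
    """
    cat = catalog or BalancerCatalog.from_tsv()
    rows = []
    for ab, sites in cat.sites.items():
        for s in sites:
            if not s.known or s.printed_delta is None:
                continue
            rec = s.recomputed_delta()
            rows.append({
                "aberration": ab, "polytene": s.polytene, "site": s.site,
                "chrom": s.chrom, "proximal": s.proximal, "distal": s.distal,
                "printed_delta": s.printed_delta, "recomputed_delta": rec,
                "consistent": rec == s.printed_delta,
            })
    return pd.DataFrame(rows)


def check_duplication_sizes(path: str | Path | None = None) -> pd.DataFrame:
    """Recompute duplicated-segment sizes as end - start from printed extents.

    A row is flagged when the printed size disagrees with the coordinate
    difference (the published 58A4-59A2 row prints 712,929 against a
    coordinate difference of 717,890; coordinates are authoritative here).
    """
    if path is None:
        path = resources.files("balancerscan.data") / "balancer_duplications.tsv"
    df = pd.read_csv(path, sep="\t", na_values="NA")
    df["size_from_coordinates"] = df["end"].astype(int) - df["start"].astype(int)
    df["consistent"] = df["size_from_coordinates"] == df["printed_size"].astype(int)
    return df
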
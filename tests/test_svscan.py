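"""Evidence extraction, clustering, assembly, placement and fingerprinting."""

import random

import pytest

from balancerscan import svscan as sv
from balancerscan.catalog import BalancerCatalog
from balancerscan.forge.segmap import revcomp

CFG = sv.SvConfig()


# ----------------------------------------------------------------- extraction

def _write_sam(path, records, chrom="c", length=100_000):
    lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{chrom}\tLN:{length}"]
    lines += records
    path.write_text("\n".join(lines) + "\n")
    return path


def test_ff_pair_across_inversion_yields_ff_evidence(tmp_path):
    # hand-projected pair across a toy inversion junction: both mates forward
    sam = _write_sam(tmp_path / "ff.sam", [
        "p\t67\tc\t1001\t60\t100M\t=\t1501\t0\t" + "A" * 100 + "\t*",
        "p\t131\tc\t1501\t60\t100M\t=\t1001\t0\t" + "A" * 100 + "\t*",
    ])
    ev, _, _ = sv.extract_evidence(sam, CFG, insert_mean=400, insert_sd=40)
    assert len(ev) == 1 and ev[0].kind == "discordant"
    assert ev[0].insert_anomaly == "FF"
    assert {ev[0].locus_a[2], ev[0].locus_b[2]} == {"+"}  # both point rightward


def test_unsorted_sam_rejected(tmp_path):
    sam = tmp_path / "u.sam"
    sam.write_text("@HD\tVN:1.6\tSO:queryname\n@SQ\tSN:c\tLN:1000\n")
    with pytest.raises(ValueError):
        sv.extract_evidence(sam, CFG, insert_mean=400, insert_sd=40)


def test_split_evidence_brackets_planted_flanks(inversion_sim):
    ev, _, _ = sv.extract_evidence(inversion_sim["sam"], CFG)
    splits = [e for e in ev if e.kind == "split"]
    truth = {tuple(sorted((j["flank_a"][:2], j["flank_b"][:2])))
             for j in inversion_sim["map"].junctions()}
    hit = {tuple(sorted((e.locus_a[:2], e.locus_b[:2]))) for e in splits}
    assert truth <= hit  # every planted junction has exact split evidence


# ----------------------------------------------------------------- clustering

def mk_split(pa, pb, chrom="c", q="r"):
    return sv.Evidence("split", q, (chrom, pa, "+"), (chrom, pb, "+"),
                       clip_length=50)


def test_tight_split_reads_form_one_cluster():
    ev = [mk_split(1000 + i, 5000 + i, q=f"r{i}") for i in range(5)]
    cl = sv.cluster_evidence(ev, 500, CFG)
    assert len(cl) == 1 and cl[0].support == (5, 0)


def test_distant_junctions_stay_separate():
    ev = ([mk_split(1000, 5000, q=f"a{i}") for i in range(3)]
          + [mk_split(11_000, 15_000, q=f"b{i}") for i in range(3)])
    assert len(sv.cluster_evidence(ev, 500, CFG)) == 2


def test_clustering_is_order_independent_vs_bruteforce():
    rnd = random.Random(5)
    ev = [mk_split(1000 + rnd.randrange(2000), 9000 + rnd.randrange(2000),
                   q=f"r{i}") for i in range(40)]

    def brute(evs, radius):
        # all-pairs single linkage oracle
        parent = list(range(len(evs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(evs)):
            for j in range(len(evs)):
                if (abs(evs[i].locus_a[1] - evs[j].locus_a[1]) <= radius
                        and abs(evs[i].locus_b[1] - evs[j].locus_b[1]) <= radius):
                    parent[find(i)] = find(j)
        groups = {}
        for i, e in enumerate(evs):
            groups.setdefault(find(i), set()).add(e.query_name)
        return {frozenset(g) for g in groups.values()}

    expected = {g for g in brute(ev, 300) if len(g) >= CFG.min_split_support}
    for seed in range(3):
        shuffled = ev[:]
        random.Random(seed).shuffle(shuffled)
        got = {frozenset(m.query_name for m in c.members)
               for c in sv.cluster_evidence(shuffled, 300, CFG)}
        assert got == expected


# ------------------------------------------------------------------- assembly

def _cluster_of(seqs_list):
    members = [sv.Evidence("split", f"q{i}", ("c", 1, "+"), ("c", 2, "+"))
               for i in range(len(seqs_list))]
    cl = sv.EvidenceCluster(members, ("c", 1, 1), ("c", 2, 2),
                            (len(members), 0), cluster_id=0)
    seqs = {(f"q{i}", 0): s for i, s in enumerate(seqs_list)}
    return cl, seqs


def test_two_read_overlap_merge():
    # exhaustive-overlap oracle: suffix 'TACGT' == prefix 'TACGT'
    cl, seqs = _cluster_of(["ACGTACGT", "TACGTAAA"])
    cfg = sv.SvConfig(min_overlap=5)
    contig = sv.assemble_cluster(cl, seqs, cfg)
    assert contig.sequence == "ACGTACGTAAA"


def test_identical_duplicate_reads_collapse():
    cl, seqs = _cluster_of(["ACGTACGTACGT"] * 4)
    contig = sv.assemble_cluster(cl, seqs, sv.SvConfig(min_overlap=5))
    assert contig.sequence == "ACGTACGTACGT" and contig.assembled


def test_tiling_reads_reconstruct_fragment_exactly():
    rnd = random.Random(7)
    frag = "".join(rnd.choice("ACGT") for _ in range(300))
    reads = [frag[i: i + 150] for i in range(0, 151, 3)]
    cl, seqs = _cluster_of(reads)
    contig = sv.assemble_cluster(cl, seqs, sv.SvConfig(min_overlap=20))
    assert contig.sequence == frag


def test_no_overlap_returns_longest_read_unassembled():
    cl, seqs = _cluster_of(["AAAACCCCAA", "GGGGAAGGTTTG"])
    contig = sv.assemble_cluster(cl, seqs, sv.SvConfig(min_overlap=8))
    assert contig.sequence == "GGGGAAGGTTTG" and not contig.assembled


# ------------------------------------------------------------------ placement

def _toy_genome(seed=3, n=20_000):
    rnd = random.Random(seed)
    return {"c": "".join(rnd.choice("ACGT") for _ in range(n))}


def test_contig_inside_one_locus_is_unplaceable():
    g = _toy_genome()
    contig = sv.Contig(g["c"][5_000:5_400], [], 0)
    p = sv.place_contig(contig, g, CFG)
    assert p.status == "unplaceable" and p.n_candidate_blocks == 1


def test_inversion_junction_contig_places_as_two_opposite_blocks():
    g = _toy_genome()
    # derivative around an inversion head junction: prefix+ then core-
    contig_seq = g["c"][4_800:5_000] + revcomp(g["c"][9_000:9_200])
    p = sv.place_contig(sv.Contig(contig_seq, [], 0), g, CFG)
    assert p.status == "placed"
    strands = sorted(b[3] for b in p.blocks)
    assert strands == ["+", "-"]


def test_low_complexity_contig_is_unplaceable():
    # two-letter tract: k-mer anchors are non-unique, as in heterochromatin
    rnd = random.Random(9)
    g = _toy_genome()
    g["c"] = g["c"][:8_000] + "".join(rnd.choice("AT") for _ in range(4_000)) \
        + g["c"][12_000:]
    contig_seq = g["c"][9_000:9_400]
    p = sv.place_contig(sv.Contig(contig_seq, [], 0), g, CFG)
    assert p.status == "unplaceable"


# -------------------------------------------------------------- junction calls

def _placement(blocks):
    return sv.Placement("placed", blocks, 2)


def _cluster_stub():
    e = sv.Evidence("split", "q", ("c", 1, "+"), ("c", 2, "+"))
    return sv.EvidenceCluster([e, e], ("c", 1, 1), ("c", 2, 2), (2, 0), 7)


def test_blunt_junction_has_delta_zero():
    # mirror-junction style: blocks abut with no lost or gained bases
    p = _placement([("c", 101, 400, "+", 1, 300), ("c", 1001, 1300, "-", 301, 600)])
    call = sv.call_junction(p, _cluster_stub())
    assert call.delta == 0 and call.kind == "rearrangement"


def test_colinear_deletion_junction_delta():
    # 153 reference bases strictly between the retained flanks are deleted
    p = _placement([("c", 101, 400, "+", 1, 300), ("c", 554, 853, "+", 301, 600)])
    call = sv.call_junction(p, _cluster_stub())
    assert call.kind == "local-indel" and call.delta == -153


def test_tandem_duplication_junction_positive_delta():
    p = _placement([("c", 301, 600, "+", 1, 300), ("c", 401, 700, "+", 301, 600)])
    call = sv.call_junction(p, _cluster_stub())
    assert call.delta == 200  # bases 401..600 present on both sides


# -------------------------------------------------------------------- pairing

def _call(fa, fb):
    return sv.JunctionCall(fa, fb, 0, (3, 0), 0)


def test_inversion_junction_pair_is_recognized():
    j1 = _call(("c", 5_000, "+"), ("c", 8_999, "+"))
    j2 = _call(("c", 5_001, "-"), ("c", 9_000, "-"))
    abs_ = sv.pair_junctions([j1, j2], CFG)
    assert len(abs_) == 1 and abs_[0].kind == "inversion"
    assert [s["delta"] for s in abs_[0].sites] == [0, 0]


def test_lone_junction_is_unpaired():
    abs_ = sv.pair_junctions([_call(("c", 5_000, "+"), ("c", 80_000, "+"))], CFG)
    assert abs_[0].kind == "complex/unpaired"


def test_mini_complex_event_groups_three_junctions(mini_world):
    calls = _truth_calls(mini_world, "SM5m")
    abs_ = sv.pair_junctions(calls, CFG)
    kinds = sorted(a.kind for a in abs_)
    assert kinds.count("inversion") == 3
    complexes = [a for a in abs_ if a.kind == "complex"]
    assert len(complexes) == 1 and len(complexes[0].junctions) == 3


# ------------------------------------------------------------- fingerprinting

def _truth_calls(world, balancer):
    calls = {}
    for j in world.manifest["junctions"][balancer]:
        if j["spacer"]:
            continue
        fa, fb = tuple(j["flank_a"]), tuple(j["flank_b"])
        key = tuple(sorted([fa, fb]))
        calls[key] = sv.JunctionCall(fa, fb, j["delta"], (5, 5), 0)
    return list(calls.values())


def _site(cat_site):
    return {"chrom": cat_site.chrom, "proximal": cat_site.proximal,
            "distal": cat_site.distal, "delta": 0}


def _aberration(catalog, name):
    return sv.AberrationCall("inversion", [],
                             sites=[_site(s) for s in catalog.matchable_sites(name)])


def test_published_catalog_identifies_sm1_and_cyo():
    cat = BalancerCatalog.from_tsv()
    sm1_calls = [_aberration(cat, a) for a in ("In(2R)Cy", "In(2LR)SM1")]
    assert sv.identify_balancer(sm1_calls, cat) == "SM1"
    # the mislabeling case: stock labeled SM6a actually carrying CyO
    cyo_calls = [_aberration(cat, a) for a in ("In(2R)Cy", "In(2LR)O")]
    assert sv.identify_balancer(cyo_calls, cat) == "CyO"
    sm6a_calls = [_aberration(cat, a)
                  for a in ("In(2R)Cy", "In(2LR)SM1", "In(2LR)O")]
    assert sv.identify_balancer(sm6a_calls, cat) == "SM6a"


def test_empty_call_list_is_unknown():
    assert sv.identify_balancer([], BalancerCatalog.from_tsv()) == "unknown"


def test_all_four_mini_balancers_fingerprint_correctly(mini_world):
    for balancer in mini_world.catalog.balancers:
        calls = _truth_calls(mini_world, balancer)
        abs_ = sv.pair_junctions(calls, CFG)
        assert sv.identify_balancer(abs_, mini_world.catalog) == balancer
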
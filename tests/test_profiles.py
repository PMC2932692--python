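"""Metagene and exon-boundary profiles against brute-force oracles,
plus the strand-mirroring invariance."""

import numpy as np
import pandas as pd
import pytest

from tilechip.models import ContractError, GeneModel
from tilechip.profiles import (
    BIN_SIZE,
    EXON_END_WINDOW,
    EXON_START_WINDOW,
    TES_WINDOW,
    TSS_WINDOWS,
    exon_boundary_profile,
    find_exon_triplets,
    metagene_profile,
    quantile_bin_genes,
)

from conftest import make_track


def _gene(i, chrom, strand, start, length, expression=None, exons=None):
    return GeneModel(
        f"g{i:03d}", chrom, strand, start, start + length,
        exons=exons or [], expression=expression,
    )


class TestQuantileBinGenes:
    def test_ten_genes_five_groups_of_two(self):
        genes = [_gene(i, "c", "+", i * 5000, 2500, expression=float(i)) for i in range(10)]
        groups = quantile_bin_genes(genes, k=5)
        sizes = pd.Series(groups).value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]
        # highest-expression genes land in the top group
        assert groups["g008"] == groups["g009"] == 4

    def test_short_genes_excluded(self):
        genes = [_gene(i, "c", "+", i * 5000, 2500, expression=float(i)) for i in range(6)]
        genes.append(_gene(99, "c", "+", 90_000, 1000, expression=50.0))
        groups = quantile_bin_genes(genes, k=3)
        assert "g099" not in groups

    def test_all_equal_expression_uses_stable_id_order(self):
        genes = [_gene(i, "c", "+", i * 5000, 2500, expression=1.0) for i in range(6)]
        groups = quantile_bin_genes(genes, k=3)
        assert [groups[f"g{i:03d}"] for i in range(6)] == [0, 0, 1, 1, 2, 2]

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(12)
        genes = [
            _gene(i, "c", "+", i * 6000, int(rng.integers(1500, 4000)),
                  expression=float(rng.normal()))
            for i in range(47)
        ]
        k = 5
        groups = quantile_bin_genes(genes, k=k)
        eligible = sorted(
            (g for g in genes if g.length > 2000),
            key=lambda g: (g.expression, g.gene_id),
        )
        expected = {}
        for gi, chunk in enumerate(np.array_split(np.arange(len(eligible)), k)):
            for j in chunk:
                expected[eligible[j].gene_id] = gi
        assert groups == expected

    def test_too_few_genes_errors(self):
        genes = [_gene(0, "c", "+", 0, 2500, expression=1.0)]
        with pytest.raises(ContractError):
            quantile_bin_genes(genes, k=5)


def _binned_oracle(track, genes, groups, anchor, lo, hi):
    """Independent per-probe nearest-bin-center accumulation."""
    n_bins = (hi - lo) // BIN_SIZE
    centers = np.array([lo + BIN_SIZE * i + BIN_SIZE / 2 for i in range(n_bins)])
    pooled = {}
    mids = ((track["start"] + track["end"]) // 2).to_numpy()
    for g in genes:
        if g.gene_id not in groups:
            continue
        a = g.tss if anchor == "TSS" else g.tes
        sel = track["chrom"].to_numpy(str) == g.chrom
        rel = np.where(g.strand == "+", mids - a, a - mids)
        for r, v, ok in zip(rel, track["value"], sel):
            if not ok or r < lo or r > hi:
                continue
            d = np.abs(centers - r)
            best = np.flatnonzero(d == d.min())[0]  # tie -> left bin
            pooled.setdefault((groups[g.gene_id], best), []).append(v)
    return pooled


class TestMetageneProfile:
    def test_constant_track_constant_bins(self):
        genes = [_gene(0, "c", "+", 5000, 3000, expression=1.0)]
        starts = np.arange(0, 12_000, 50)
        track = make_track(["c"] * len(starts), starts, np.full(len(starts), 2.5))
        prof = metagene_profile(track, genes, {"g000": 0}, anchor="TSS")
        assert np.allclose(prof.mean[0][prof.n[0] > 0], 2.5)
        assert np.allclose(prof.ci[0][prof.n[0] > 0], 0.0)

    def test_single_probe_assigned_to_covering_bin(self):
        genes = [_gene(0, "c", "+", 5000, 3000, expression=1.0)]
        track = make_track(["c"], [5000], [1.7])  # midpoint 5025 = TSS + 25
        prof = metagene_profile(track, genes, {"g000": 0}, anchor="TSS")
        (bin_idx,) = np.flatnonzero(prof.n[0])
        assert prof.bin_centers[bin_idx] == 25  # the 0..+50 bin
        assert prof.mean[0, bin_idx] == 1.7

    def test_empty_group_errors(self):
        genes = [_gene(0, "c", "+", 5000, 3000)]
        track = make_track(["c"], [5000], [1.0])
        with pytest.raises(ContractError, match="group"):
            metagene_profile(track, genes, {"absent_gene": 0}, anchor="TSS")

    def test_methods_convention_shifts_window(self):
        genes = [_gene(0, "c", "+", 5000, 3000, expression=1.0)]
        track = make_track(["c"], [3600], [1.0])  # midpoint 3625 = TSS - 1375
        results = metagene_profile(track, genes, {"g000": 0}, convention="results")
        methods = metagene_profile(track, genes, {"g000": 0}, convention="methods")
        assert results.n.sum() == 0  # outside -1000..+1500
        assert methods.n.sum() == 1  # inside -1500..+1000

    @pytest.mark.parametrize("anchor", ["TSS", "TES"])
    def test_matches_brute_force_oracle_200_genes(self, anchor):
        rng = np.random.default_rng(21)
        genes = []
        pos = 2000
        for i in range(200):
            length = int(rng.integers(2100, 5000))
            genes.append(
                _gene(i, "c", rng.choice(["+", "-"]), pos, length, expression=float(rng.normal()))
            )
            pos += length + int(rng.integers(600, 1500))
        starts = np.arange(0, pos + 3000, 50)
        track = make_track(["c"] * len(starts), starts, rng.normal(0, 1, len(starts)))
        groups = quantile_bin_genes(genes, k=5)
        lo, hi = TSS_WINDOWS["results"] if anchor == "TSS" else TES_WINDOW
        prof = metagene_profile(track, genes, groups, anchor=anchor)
        pooled = _binned_oracle(track, genes, groups, anchor, lo, hi)
        for gi in range(5):
            for bi in range(50):
                vals = pooled.get((gi, bi), [])
                assert prof.n[gi, bi] == len(vals)
                if vals:
                    assert prof.mean[gi, bi] == pytest.approx(np.mean(vals), abs=1e-9)
                    sem = np.std(vals) / np.sqrt(len(vals))
                    assert prof.ci[gi, bi] == pytest.approx(1.96 * sem, abs=1e-9)

    def test_strand_mirroring_invariance(self):
        rng = np.random.default_rng(30)
        L = 100_000
        genes = []
        pos = 2000
        for i in range(40):
            length = int(rng.integers(2100, 4000))
            genes.append(
                _gene(i, "c", rng.choice(["+", "-"]), pos, length, expression=float(rng.normal()))
            )
            pos += length + 1000
        starts = np.arange(0, L, 50)
        track = make_track(["c"] * len(starts), starts, rng.normal(0, 1, len(starts)))
        groups = quantile_bin_genes(genes, k=4)
        # mirror: coordinate c -> L - c, strands flipped
        mirrored_genes = [
            GeneModel(
                g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                L - g.tx_end, L - g.tx_start, expression=g.expression,
            )
            for g in genes
        ]
        mirrored_track = track.copy()
        mirrored_track["start"] = L - track["end"]
        mirrored_track["end"] = L - track["start"]
        mirrored_track = mirrored_track.sort_values("start", ignore_index=True)
        for anchor in ("TSS", "TES"):
            a = metagene_profile(track, genes, groups, anchor=anchor)
            b = metagene_profile(mirrored_track, mirrored_genes, groups, anchor=anchor)
            assert np.array_equal(a.n, b.n)
            assert np.allclose(a.mean, b.mean, equal_nan=True, atol=1e-12)


class TestExonTriplets:
    def test_single_exon_gene_yields_nothing(self):
        g = _gene(0, "c", "+", 0, 2000)
        assert find_exon_triplets([g]) == []

    def test_three_exons_with_long_introns_yield_one(self):
        exons = [(0, 400), (750, 1150), (1500, 1900)]
        g = GeneModel("g", "c", "+", 0, 1900, exons=exons)
        (t,) = find_exon_triplets([g])
        assert t.exon == (750, 1150)
        assert t.intron_up == (400, 750) and t.intron_down == (1150, 1500)

    def test_short_intron_disqualifies(self):
        exons = [(0, 400), (600, 1000), (1350, 1750)]  # first intron 200 bp
        g = GeneModel("g", "c", "+", 0, 1750, exons=exons)
        assert find_exon_triplets([g]) == []

    def test_minus_strand_orientation(self):
        exons = [(0, 400), (750, 1150), (1500, 1900)]
        g = GeneModel("g", "c", "-", 0, 1900, exons=exons)
        (t,) = find_exon_triplets([g])
        assert t.intron_up == (1150, 1500)  # transcription runs right to left
        assert t.exon_start == 1150 and t.exon_end == 750

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        genes = []
        pos = 0
        for i in range(30):
            n_ex = int(rng.integers(1, 6))
            segs = rng.integers(150, 700, size=2 * n_ex - 1)
            edges = np.concatenate([[0], np.cumsum(segs)])
            exons = [(pos + int(edges[2 * k]), pos + int(edges[2 * k + 1])) for k in range(n_ex)]
            genes.append(
                GeneModel(f"g{i}", "c", rng.choice(["+", "-"]), pos, pos + int(edges[-1]), exons=exons)
            )
            pos += int(edges[-1]) + 500
        triplets = find_exon_triplets(genes, min_len=300)
        expected = 0
        for g in genes:
            for j in range(1, len(g.exons) - 1):
                e = g.exons[j]
                iu = (g.exons[j - 1][1], g.exons[j][0])
                idn = (g.exons[j][1], g.exons[j + 1][0])
                if min(e[1] - e[0], iu[1] - iu[0], idn[1] - idn[0]) >= 300:
                    expected += 1
        assert len(triplets) == expected


class TestExonBoundaryProfile:
    @staticmethod
    def _triplet_gene(strand="+"):
        exons = [(0, 400), (800, 1300), (1700, 2100)]
        return GeneModel("g", "c", strand, 0, 2100, exons=exons)

    def test_constant_track_with_subtraction_gives_zero(self):
        g = self._triplet_gene()
        triplets = find_exon_triplets([g])
        starts = np.arange(0, 2100, 50)
        track = make_track(["c"] * len(starts), starts, np.full(len(starts), 3.0))
        st, en, skipped = exon_boundary_profile(track, triplets, {"g": 0}, baseline_subtract=True)
        assert skipped == 0
        assert np.allclose(st.mean[st.n > 0], 0.0, atol=1e-12)
        assert np.allclose(en.mean[en.n > 0], 0.0, atol=1e-12)

    def test_step_function_shows_exon_minus_intron(self):
        g = self._triplet_gene()
        triplets = find_exon_triplets([g])
        starts = np.arange(0, 2100, 50)
        mids = starts + 25
        values = np.where((mids >= 800) & (mids < 1300), 5.0, 1.0)
        # make the flanking exons intron-valued so only the central exon steps up
        values[(mids < 400) | (mids >= 1700)] = 1.0
        track = make_track(["c"] * len(starts), starts, values)
        st, _, _ = exon_boundary_profile(track, triplets, {"g": 0}, baseline_subtract=True)
        exonic_bins = st.bin_centers > 0
        intronic_bins = st.bin_centers < 0
        assert np.allclose(st.mean[0][exonic_bins & (st.n[0] > 0)], 4.0)
        assert np.allclose(st.mean[0][intronic_bins & (st.n[0] > 0)], 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        genes, pos = [], 0
        for i in range(40):
            n_ex = int(rng.integers(2, 5))
            segs = rng.integers(320, 800, size=2 * n_ex - 1)
            edges = np.concatenate([[0], np.cumsum(segs)])
            exons = [(pos + int(edges[2 * k]), pos + int(edges[2 * k + 1])) for k in range(n_ex)]
            genes.append(
                GeneModel(f"g{i}", "c", rng.choice(["+", "-"]), pos, pos + int(edges[-1]), exons=exons)
            )
            pos += int(edges[-1]) + 700
        starts = np.arange(0, pos, 50)
        track = make_track(["c"] * len(starts), starts, rng.normal(size=len(starts)))
        triplets = find_exon_triplets(genes)
        groups = {g.gene_id: i % 3 for i, g in enumerate(genes)}
        st, en, _ = exon_boundary_profile(track, triplets, groups, baseline_subtract=True)
        mids = ((track["start"] + track["end"]) // 2).to_numpy()
        values = track["value"].to_numpy()
        for prof, window, use_start in ((st, EXON_START_WINDOW, True), (en, EXON_END_WINDOW, False)):
            lo, hi = window
            n_bins = (hi - lo) // BIN_SIZE
            centers = np.array([lo + BIN_SIZE * i + BIN_SIZE / 2 for i in range(n_bins)])
            pooled = {}
            for t in triplets:
                intronic = np.zeros(len(mids), bool)
                for s, e in (t.intron_up, t.intron_down):
                    intronic |= (mids >= s) & (mids < e)
                if not intronic.any():
                    continue
                baseline = values[intronic].mean()
                a = t.exon_start if use_start else t.exon_end
                rel = mids - a if t.strand == "+" else a - mids
                for r, v in zip(rel, values):
                    if r < lo or r > hi:
                        continue
                    d = np.abs(centers - r)
                    best = np.flatnonzero(d == d.min())[0]
                    pooled.setdefault((groups[t.gene_id], best), []).append(v - baseline)
            for gi in range(3):
                for bi in range(n_bins):
                    vals = pooled.get((gi, bi), [])
                    assert prof.n[gi, bi] == len(vals)
                    if vals:
                        assert prof.mean[gi, bi] == pytest.approx(np.mean(vals), abs=1e-9)
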
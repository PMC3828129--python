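import numpy as np
import pytest

from foldspace.descriptors import (
    DomainStructure,
    ResidueAnnotation,
    amino_acid_propensities,
    buried_fraction_norm,
    contact_counts,
    describe_domain,
    disulphide_class,
    hydrophobicity,
    load_omh_scale,
    nonlocal_contacts_norm,
    radius_of_gyration,
    read_descriptors,
    strand_direction_label,
    summarize_superfamily,
    write_descriptors,
)
from foldspace.motifs import SheetTopology, Strand
from foldspace.synth import synthetic_domain


def _random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=50.0, size=3)
    return R, t


def _domain(seq, coords, anns, topo=None, sf="SF1", did="D1"):
    return DomainStructure(
        domain_id=did, superfamily_id=sf, sequence=seq,
        ca_coords=coords, annotations=anns, sheet_topology=topo,
    )


class TestRadiusOfGyration:
    def test_circle_equals_radius(self):
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        r = 7.5
        center = np.array([3.0, -2.0, 11.0])
        pts = center + np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)]
        )
        assert radius_of_gyration(pts) == pytest.approx(r)

    def test_two_points(self):
        pts = np.array([[0, 0, 0], [0, 0, 6.0]])
        assert radius_of_gyration(pts) == pytest.approx(3.0)

    def test_matches_direct_formula(self, rng):
        pts = rng.normal(size=(50, 3)) * 10
        centered = pts - pts.mean(axis=0)
        expect = np.sqrt((centered**2).sum(axis=1).mean())
        assert radius_of_gyration(pts) == pytest.approx(expect, rel=1e-12)

    def test_rigid_invariance(self, rng):
        pts = rng.normal(size=(40, 3)) * 8
        rg0 = radius_of_gyration(pts)
        for _ in range(20):
            R, t = _random_rigid(rng)
            assert radius_of_gyration(pts @ R.T + t) == pytest.approx(
                rg0, rel=1e-9
            )

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((1, 3)))


class TestContacts:
    def test_straight_chain_has_no_nonlocal_contacts(self):
        pts = np.column_stack(
            [3.8 * np.arange(30), np.zeros(30), np.zeros(30)]
        )
        total, nonloc = contact_counts(pts, 8.0, 5)
        assert nonloc == 0 and total == 2 * 30 - 3  # |i-j| in {1,2}

    def test_triangle_all_pairs(self):
        pts = np.array([[0, 0, 0], [5, 0, 0], [2.5, 5 * np.sqrt(3) / 2, 0]])
        total, nonloc = contact_counts(pts, 8.0, 1)
        assert total == 3 and nonloc == 3

    def test_matches_all_pairs_brute_force(self, rng):
        pts = rng.normal(size=(60, 3)) * 6
        total, nonloc = contact_counts(pts, 8.0, 5)
        bt = bn = 0
        for i in range(60):
            for j in range(i + 1, 60):
                if np.linalg.norm(pts[i] - pts[j]) <= 8.0:
                    bt += 1
                    if j - i >= 5:
                        bn += 1
        assert (total, nonloc) == (bt, bn)

    def test_contact_counts_rigid_invariance(self, rng):
        pts = rng.normal(size=(45, 3)) * 7
        ref = contact_counts(pts, 8.0, 5)
        for _ in range(10):
            R, t = _random_rigid(rng)
            assert contact_counts(pts @ R.T + t, 8.0, 5) == ref


class TestNormalizedDescriptors:
    def _dom_with_coords(self, coords):
        n = len(coords)
        anns = [
            ResidueAnnotation(ss_element="coil", relative_exposure=50.0)
            for _ in range(n)
        ]
        return _domain("A" * n, coords, anns)

    def test_zero_nonlocal_gives_zero(self):
        pts = np.column_stack([3.8 * np.arange(20), np.zeros(20), np.zeros(20)])
        assert nonlocal_contacts_norm(self._dom_with_coords(pts)) == 0.0

    def test_scaling_shrinks_normalized_contacts(self, rng):
        pts = rng.normal(size=(50, 3)) * 5
        d1 = self._dom_with_coords(pts)
        d2 = self._dom_with_coords(pts * 2.0)
        v1 = nonlocal_contacts_norm(d1)
        v2 = nonlocal_contacts_norm(d2)
        if v1 > 0:
            assert v2 <= v1 / 2 + 1e-12

    def test_known_arithmetic(self):
        # 30 of 100 residues buried, Rg 15 A -> 0.3 / 15 = 0.02
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(100, 3))
        pts = (pts - pts.mean(0))
        pts *= 15.0 / radius_of_gyration(pts)
        anns = [
            ResidueAnnotation(
                ss_element="coil",
                relative_exposure=3.0 if i < 30 else 60.0,
            )
            for i in range(100)
        ]
        d = _domain("A" * 100, pts, anns)
        assert buried_fraction_norm(d, 7.0) == pytest.approx(0.02)

    def test_all_exposed_gives_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3)) * 5
        anns = [
            ResidueAnnotation(ss_element="coil", relative_exposure=100.0)
            for _ in range(20)
        ]
        assert buried_fraction_norm(_domain("A" * 20, pts, anns)) == 0.0

    def test_missing_exposure_listed(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3)) * 5
        anns = [
            ResidueAnnotation(
                ss_element="coil",
                relative_exposure=None if i == 4 else 50.0,
            )
            for i in range(12)
        ]
        with pytest.raises(ValueError, match="4"):
            buried_fraction_norm(_domain("A" * 12, pts, anns))


class TestHydrophobicity:
    def test_homopolymer_equals_scale_value(self):
        scale = load_omh_scale()
        assert hydrophobicity("FFFF") == pytest.approx(scale["F"])

    def test_two_residue_midpoint(self):
        scale = load_omh_scale()
        assert hydrophobicity("IL") == pytest.approx(
            (scale["I"] + scale["L"]) / 2
        )

    def test_matches_independent_mean(self, rng):
        scale = load_omh_scale()
        seq = "".join(rng.choice(list(scale), size=100))
        expect = sum(scale[a] for a in seq) / 100
        assert hydrophobicity(seq) == pytest.approx(expect)

    def test_unknown_residue_policy(self):
        with pytest.raises(KeyError):
            hydrophobicity("AXA")
        scale = load_omh_scale()
        mean = float(np.mean(list(scale.values())))
        v = hydrophobicity("X", map_unknown_to_mean=True)
        assert v == pytest.approx(mean)


class TestStrandDirection:
    def _sheet(self, orientations):
        strands = [
            Strand(f"S{i + 1}", sequence_order=i + 1, spatial_position=i + 1)
            for i in range(len(orientations) + 1)
        ]
        pairings = [
            (f"S{i + 1}", f"S{i + 2}", o) for i, o in enumerate(orientations)
        ]
        return SheetTopology("sheet", strands, pairings)

    def _dom(self, ss_plan, topo):
        n = len(ss_plan)
        rng = np.random.default_rng(0)
        pts = np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
        anns = [
            ResidueAnnotation(ss_element=e, strand_id=s, relative_exposure=50.0)
            for e, s in ss_plan
        ]
        return _domain("A" * n, pts, anns, topo=topo)

    def test_all_helix_not_applicable(self):
        plan = [("helix", None)] * 30
        assert strand_direction_label(self._dom(plan, None)) == "not_applicable"

    def test_antiparallel_hairpin(self):
        plan = [("strand", "S1")] * 5 + [("coil", None)] * 2 + [
            ("strand", "S2")
        ] * 5
        topo = self._sheet(["antiparallel"])
        assert strand_direction_label(self._dom(plan, topo)) == "antiparallel"

    def test_sixty_forty_mix_is_mixed(self):
        # S1 paired parallel+antiparallel; tally 60/40 below 0.7 majority
        strands = [
            Strand("S1", 1, 1), Strand("S2", 2, 2), Strand("S3", 3, 0)
        ]
        topo = SheetTopology(
            "sheet", strands,
            [("S1", "S2", "parallel"), ("S3", "S1", "antiparallel")],
        )
        plan = (
            [("strand", "S1")] * 4
            + [("strand", "S2")] * 4
            + [("strand", "S3")] * 2
        )
        # per-residue votes: S1 res get 1 par + 1 anti each, S2 par, S3 anti
        label = strand_direction_label(
            self._dom(plan, topo), majority_threshold=0.7
        )
        assert label == "mixed"


class TestDisulphides:
    def _dom(self, has_bond, did):
        n = 12
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(n, 3)) * 5
        anns = [
            ResidueAnnotation(
                ss_element="coil", relative_exposure=50.0,
                disulphide_partner=(5 if has_bond and i == 2 else
                                    2 if has_bond and i == 5 else None),
            )
            for i in range(n)
        ]
        return _domain("A" * n, pts, anns, did=did)

    def test_majority_with(self):
        doms = [self._dom(True, "a"), self._dom(True, "b"), self._dom(False, "c")]
        assert disulphide_class(doms) == "with"

    def test_none_without(self):
        assert disulphide_class([self._dom(False, str(i)) for i in range(4)]) == "without"

    def test_minority_is_ambiguous(self):
        doms = [self._dom(i == 0, str(i)) for i in range(4)]
        assert disulphide_class(doms) == "ambiguous"


class TestPropensities:
    def test_whole_set_group_is_unity(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFG"), size=50)) for _ in range(10)]
        df = amino_acid_propensities({"all": seqs}, background=seqs)
        assert np.allclose(df["propensity"], 1.0)

    def test_polyala_group_extreme(self):
        bg = ["AAAA", "CCCC", "DDDD", "GGGG"]
        df = amino_acid_propensities({"grp": ["AAAA"]}, background=bg)
        row = df[(df.amino_acid == "A") & (df.group == "grp")].iloc[0]
        assert row.propensity == pytest.approx(4.0)  # N/n_A = 16/4

    def test_conservation_over_partition(self, rng):
        groups = {
            "g1": ["".join(rng.choice(list("ACDE"), size=40)) for _ in range(5)],
            "g2": ["".join(rng.choice(list("ACDE"), size=40)) for _ in range(3)],
            "g3": ["".join(rng.choice(list("ACDE"), size=40)) for _ in range(7)],
        }
        bg = [s for seqs in groups.values() for s in seqs]
        df = amino_acid_propensities(groups, background=bg)
        N = sum(len(s) for s in bg)
        for aa in "ACDE":
            total = 0.0
            for g, seqs in groups.items():
                ng = sum(len(s) for s in seqs)
                row = df[(df.amino_acid == aa) & (df.group == g)].iloc[0]
                total += (ng / N) * row.propensity
            assert total == pytest.approx(1.0)

    def test_planted_cys_enrichment_recovered(self):
        # two groups of 50,000 residues; Cys planted at 1.3-fold propensity
        # in group A (cf. the observed new-born Cys propensity ~1.31)
        rng = np.random.default_rng(42)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        base = np.ones(20) / 20
        ci = aas.index("C")
        pa = base.copy()
        pa[ci] = base[ci] * 13 / 7     # so 2 pA / (pA + pB) = 1.3
        pa /= pa.sum()
        pb = base.copy()
        pb[ci] = base[ci] * 1.0
        pb /= pb.sum()
        seq_a = "".join(rng.choice(aas, size=50_000, p=pa))
        seq_b = "".join(rng.choice(aas, size=50_000, p=pb))
        df = amino_acid_propensities(
            {"A": [seq_a], "B": [seq_b]}, background=[seq_a, seq_b]
        )
        row = df[(df.amino_acid == "C") & (df.group == "A")].iloc[0]
        assert 1.25 <= row.propensity <= 1.35
        # sign consistency: enriched in A implies depleted in complement
        other = df[(df.amino_acid == "C") & (df.group == "B")].iloc[0]
        assert other.propensity < 1.0


class TestSummaries:
    def _dom(self, sf, length, seed):
        return synthetic_domain(
            [("helix", max(10, length - 10)), ("coil", 10)],
            seed=seed, domain_id=f"{sf}_{seed}", superfamily_id=sf,
        )

    def test_single_domain_summary_matches_record(self):
        d = self._dom("SFX", 40, 1)
        rec = describe_domain(d)
        s = summarize_superfamily([d])
        assert s.mean_length == rec.length
        assert s.mean_rg == pytest.approx(rec.rg)
        assert s.mean_hydrophobicity == pytest.approx(rec.hydrophobicity)

    def test_mean_length(self):
        d1 = self._dom("SFX", 100, 1)
        d2 = self._dom("SFX", 200, 2)
        s = summarize_superfamily([d1, d2])
        assert s.mean_length == pytest.approx((len(d1) + len(d2)) / 2)

    def test_majority_strand_label(self):
        from foldspace.descriptors import DescriptorRecord

        recs = [
            DescriptorRecord(
                domain_id=f"d{i}", superfamily_id="SFX", length=50, rg=10.0,
                total_contacts=10, nonlocal_contacts=2,
                nonlocal_contacts_norm=0.2, buried_norm=0.02,
                hydrophobicity=0.0, strand_label=lab, has_disulphide=False,
            )
            for i, lab in enumerate(["parallel", "parallel", "antiparallel"])
        ]
        doms = [self._dom("SFX", 50, i) for i in range(3)]
        s = summarize_superfamily(doms, records=recs)
        assert s.strand_label == "parallel"

    def test_descriptor_tsv_round_trip(self, tmp_path):
        doms = [self._dom("SFY", 60, i) for i in range(3)]
        recs = [describe_domain(d) for d in doms]
        path = tmp_path / "desc.tsv"
        write_descriptors(recs, path)
        back = read_descriptors(path)
        assert back == recs
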
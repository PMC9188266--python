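"""Homology-model acceptance criteria and candidate selection."""

from dataclasses import replace
from datetime import date

import numpy as np
import pytest

from dockmap import synth
from dockmap.errors import ContractError
from dockmap.model_qc import (ModelMetadata, QCReport, RepresentativeEntry,
                              ca_gap_violations, check_length_eligible,
                              missing_segments, qc_model, select_hit,
                              select_representative)


def _chain(n=64, seed=0, start=1):
    rng = np.random.default_rng(seed)
    return synth.chain_from_ca(synth.serpentine_ca(n),
                               synth.random_sequence(n, rng), "A",
                               start_number=start)


class TestLengthEligibility:
    @pytest.mark.parametrize("length,ok", [(500, True), (501, False), (1, True)])
    def test_boundary(self, length, ok):
        assert check_length_eligible(length) is ok

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            check_length_eligible(0)


class TestMissingSegments:
    def test_full_coverage(self):
        assert missing_segments(_chain(64), 64) == []

    def test_terminal_run_of_31_fails_rule(self):
        ch = synth.delete_segment(_chain(64), 1, 31)
        runs = missing_segments(ch, 64)
        assert runs == [(1, 31)]
        longest = max(e - s + 1 for s, e in runs)
        assert longest > 30  # 31-residue N-terminal gap violates the rule

    def test_internal_run_of_30_passes_rule(self):
        ch = synth.delete_segment(_chain(64), 20, 49)
        runs = missing_segments(ch, 64)
        assert runs == [(20, 49)]
        assert max(e - s + 1 for s, e in runs) == 30  # 30 is not > 30

    def test_runs_partition_missing_positions(self):
        # counting oracle: runs exactly cover the complement of modeled positions
        rng = np.random.default_rng(5)
        for _ in range(20):
            ch = _chain(60, seed=int(rng.integers(1e6)))
            drop = rng.choice(np.arange(1, 61), size=15, replace=False)
            kept = [r for r in ch.residues if r.number not in drop]
            ch = replace(ch, residues=kept)
            runs = missing_segments(ch, 60)
            covered = {p for s, e in runs for p in range(s, e + 1)}
            assert covered == set(drop.tolist())

    def test_unrenumbered_chain_rejected(self):
        with pytest.raises(ContractError):
            missing_segments(_chain(64, start=100), 64)


class TestCaGapFormula:
    def _pair_chain(self, numbers, distance):
        rng = np.random.default_rng(0)
        coords = np.array([[0, 0, 0], [distance, 0, 0]], dtype=float)
        ch = synth.chain_from_ca(coords, synth.random_sequence(2, rng), "A")
        for r, n in zip(ch.residues, numbers):
            r.number = n
        return ch

    @pytest.mark.parametrize("numbers,distance,violates", [
        ((1, 2), 3.8, False),    # g=1, threshold 5.0
        ((1, 2), 5.0, False),    # exactly at threshold
        ((1, 2), 5.1, True),     # just above
        ((1, 4), 12.0, False),   # g=3, threshold 12.6
        ((1, 4), 12.7, True),
    ])
    def test_threshold_formula(self, numbers, distance, violates):
        viols = ca_gap_violations(self._pair_chain(numbers, distance))
        assert bool(viols) is violates
        if violates:
            ni, nj, d, thr = viols[0]
            assert (ni, nj) == numbers
            assert thr == pytest.approx(3.8 * (nj - ni) + 1.2)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        ch = _chain(50, seed=3)
        # stretch a random subset of bonds
        coords = ch.ca_coords()
        coords[25:] += np.array([4.0, 0.0, 0.0])
        ch2 = synth.chain_from_ca(coords, synth.random_sequence(50, rng), "A")
        viols = ca_gap_violations(ch2)
        expected = []
        cas = [(r.number, r.ca.coord) for r in ch2.residues]
        for (ni, ci), (nj, cj) in zip(cas, cas[1:]):
            d = float(np.linalg.norm(cj - ci))
            if d > 3.8 * (nj - ni) + 1.2:
                expected.append((ni, nj))
        assert [(v[0], v[1]) for v in viols] == expected
        assert expected  # the stretch actually created at least one


class TestQcModel:
    def _meta(self, **kw):
        base = dict(confidence=95.0, template_identity=40.0, target_length=64)
        base.update(kw)
        return ModelMetadata(**base)

    def test_compact_full_coverage_passes(self):
        rep = qc_model(_chain(), self._meta(), 64)
        assert rep.overall_pass
        assert set(rep.checks) == {"confidence", "identity", "length_eligible",
                                   "missing_segment", "ca_gap", "rg_ratio",
                                   "anisotropy"}

    def test_confidence_90_inclusive_89_fails(self):
        assert qc_model(_chain(), self._meta(confidence=90.0), 64).overall_pass
        rep = qc_model(_chain(), self._meta(confidence=89.0), 64)
        assert rep.failed() == ["confidence"]

    def test_identity_strictly_greater_than_20(self):
        assert qc_model(_chain(), self._meta(template_identity=21.0), 64).overall_pass
        rep = qc_model(_chain(), self._meta(template_identity=20.0), 64)
        assert rep.failed() == ["identity"]

    def test_elongated_model_fails_anisotropy(self, rng):
        helix = synth.chain_from_ca(synth.helix_ca(60),
                                    synth.random_sequence(60, rng), "A")
        rep = qc_model(helix, self._meta(target_length=60), 60)
        assert "anisotropy" in rep.failed()

    def test_banana_model_fails_rg_ratio(self, rng):
        arc = synth.chain_from_ca(synth.arc_ca(40),
                                  synth.random_sequence(40, rng), "A")
        rep = qc_model(arc, self._meta(target_length=40), 40)
        assert "rg_ratio" in rep.failed()

    def test_monotone_in_each_metric(self):
        # improving one metric never flips pass -> fail
        rep_low = qc_model(_chain(), self._meta(confidence=91.0), 64)
        rep_high = qc_model(_chain(), self._meta(confidence=99.0), 64)
        assert rep_low.overall_pass <= rep_high.overall_pass
        rep_id = qc_model(_chain(), self._meta(template_identity=95.0), 64)
        assert rep_low.overall_pass <= rep_id.overall_pass


class TestSelectHit:
    def _hits(self, specs):
        hits, qcs = [], []
        for rank, (passes, human, method) in enumerate(specs, start=1):
            hits.append(ModelMetadata(confidence=95, template_identity=40,
                                      rank=rank, template_species_human=human,
                                      template_method=method))
            rep = QCReport()
            from dockmap.model_qc import CheckResult
            rep.checks["all"] = CheckResult("all", passes)
            qcs.append(rep)
        return hits, qcs

    def test_default_top_passing(self):
        hits, qcs = self._hits([(True, False, "xray")] * 5)
        assert select_hit(hits, qcs).rank == 1

    def test_human_xray_override(self):
        hits, qcs = self._hits([(True, False, "xray"), (False, True, "xray"),
                                (True, True, "xray")])
        assert select_hit(hits, qcs).rank == 3

    def test_human_nmr_not_overriding(self):
        hits, qcs = self._hits([(True, False, "xray"), (True, True, "nmr")])
        assert select_hit(hits, qcs).rank == 1

    def test_cryoem_qualifies_for_override(self):
        hits, qcs = self._hits([(True, False, "xray"), (True, True, "cryoem")])
        assert select_hit(hits, qcs).rank == 2

    def test_none_when_nothing_passes(self):
        hits, qcs = self._hits([(False, False, "xray")] * 3)
        assert select_hit(hits, qcs) is None
        assert select_hit([], []) is None

    def test_only_top20_considered(self):
        specs = [(False, False, "xray")] * 20 + [(True, False, "xray")]
        hits, qcs = self._hits(specs)
        assert select_hit(hits, qcs) is None


def _random_entries(rng, n):
    methods = ["xray", "cryoem", "nmr"]
    out = []
    for k in range(n):
        m = methods[int(rng.integers(3))]
        out.append(RepresentativeEntry(
            entry_id=f"e{k}",
            coverage=float(rng.choice([0.5, 0.79, 0.80, 0.85, 0.85, 0.9, 1.0])),
            missing_count=int(rng.integers(0, 4)),
            method=m,
            resolution=None if m == "nmr" else float(rng.choice([1.5, 2.0, 2.5, 3.0])),
            deposition_date=date(2000 + int(rng.integers(0, 22)), 1, 1)))
    return out


class TestSelectRepresentative:
    def test_single_qualifying_entry(self):
        e = RepresentativeEntry("x", 0.85, 0, "xray", 2.0, date(2020, 1, 1))
        assert select_representative([e]) is e

    def test_coverage_below_80_routes_to_modeling(self):
        e = RepresentativeEntry("x", 0.79, 0, "xray", 1.0, date(2020, 1, 1))
        assert select_representative([e]) is None

    def test_method_precedes_resolution(self):
        xray = RepresentativeEntry("x", 0.9, 0, "xray", 2.5, date(2020, 1, 1))
        em = RepresentativeEntry("e", 0.9, 0, "cryoem", 2.0, date(2020, 1, 1))
        assert select_representative([em, xray]) is xray

    def test_matches_brute_force_on_random_tables(self):
        # exhaustive oracle: full sort by the stated lexicographic key
        prio = {"xray": 0, "cryoem": 1, "nmr": 2}
        rng = np.random.default_rng(17)
        for _ in range(300):
            entries = _random_entries(rng, int(rng.integers(1, 8)))
            chosen = select_representative(entries)
            eligible = [e for e in entries if e.coverage >= 0.80]
            if not eligible:
                assert chosen is None
                continue
            oracle = sorted(eligible, key=lambda e: (
                -e.coverage, e.missing_count, prio[e.method],
                e.resolution if e.resolution is not None else float("inf"),
                -e.deposition_date.toordinal(), e.entry_id))[0]
            assert chosen is oracle
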
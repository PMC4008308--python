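"""Excision, precursor criteria, pseudo filter, status calls, profiling."""

import numpy as np
import pytest

from exomir.config import ConfigError, PipelineConfig
from exomir.discover import (HairpinCandidate, arm_table, evaluate_candidate,
                             excise_candidates, load_toy_references,
                             match_known, mipred_filter, profile_precursor)
from exomir.genome_map import TagAlignment
from exomir.io import SequenceRecord, revcomp
from exomir.preprocess import SmallRNATag
from exomir.rnafold import fold_mfe
from exomir.simulate import match_mature_to_truth, score_discovery


def _mk_candidate(seq, mature_interval, placements=None, star=None):
    ms, me = mature_interval
    tag = SmallRNATag("t1", seq[ms:me], 100)
    return HairpinCandidate(
        candidate_id="c1", chrom="chr1", start=0, end=len(seq), strand="+",
        seq=seq, placements=placements or [(tag, ms, me)],
        mature_tag=tag, mature_interval=mature_interval, star_interval=star,
    )


STEM = "GCATTAGACCGTTGAATCGAT"          # 21-nt arm used by several tests


def _hairpin_candidate(loop_len=12, flank=30, seed=10):
    rng = np.random.default_rng(seed)
    loop = "".join(rng.choice(list("AT"), loop_len))
    flank5 = "".join(rng.choice(list("ACGT"), flank))
    flank3 = "".join(rng.choice(list("ACGT"), flank))
    seq = flank5 + STEM + loop + revcomp(STEM) + flank3
    return _mk_candidate(seq, (flank, flank + len(STEM)))


class TestExcision:
    def _alns(self, positions, chrom="chr1", strand="+", length=21):
        tags, alns = {}, []
        for i, pos in enumerate(positions):
            tag = SmallRNATag(f"t{i}", "A" * length, 10 + i)
            tags[tag.tag_id] = tag
            alns.append(TagAlignment(tag.tag_id, chrom, pos, pos + length, strand))
        return tags, alns

    def test_stacked_alignments_form_one_locus(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2_000))}
        tags, alns = self._alns([500] * 50)
        cands = excise_candidates(alns, tags, genome)
        assert len(cands) == 1

    def test_distant_stacks_form_two_loci(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2_000))}
        tags, alns = self._alns([500, 700])
        cands = excise_candidates(alns, tags, genome)
        assert len(cands) == 2

    def test_window_and_flanks_are_applied(self):
        rng = np.random.default_rng(0)
        cfg = PipelineConfig()
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2_000))}
        tags, alns = self._alns([900])
        (cand,) = excise_candidates(alns, tags, genome, cfg)
        assert len(cand.seq) == cfg.excise_window + 2 * cfg.flank_len

    def test_every_planted_precursor_yields_a_candidate(self, small_run):
        truth = small_run["truth"]
        cands = small_run["result"].candidates
        for prec in truth.precursors:
            for loc in prec.loci:
                assert any(
                    c.chrom == loc.chrom and c.start < loc.end and loc.start < c.end
                    and c.strand == loc.strand
                    for c in cands
                ), prec.precursor_id


class TestEvaluate:
    def test_planted_hairpin_passes_all_criteria(self):
        cand = evaluate_candidate(_hairpin_candidate())
        assert cand.passed, [(d.criterion, d.value) for d in cand.decisions
                             if not d.passed]

    @pytest.mark.parametrize("bad_len", [17, 27])
    def test_mature_length_window(self, bad_len):
        cand = _hairpin_candidate()
        ms = cand.mature_interval[0]
        cand.mature_interval = (ms, ms + bad_len)
        cand.mature_tag = SmallRNATag("t1", cand.seq[ms:ms + bad_len], 100)
        cand = evaluate_candidate(cand)
        failed = {d.criterion for d in cand.decisions if not d.passed}
        assert "mature_length" in failed

    def test_weak_fold_fails_the_energy_criterion(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("AT"), 60))  # AT-only folds weakly
        cand = _mk_candidate(seq, (20, 41))
        cand = evaluate_candidate(cand)
        failed = {d.criterion for d in cand.decisions if not d.passed}
        assert "precursor_mfe" in failed or not cand.passed

    def test_wide_loop_fails_the_arm_gap_criterion(self):
        cand = evaluate_candidate(_hairpin_candidate(loop_len=45))
        failed = {d.criterion for d in cand.decisions if not d.passed}
        assert "arm_gap" in failed
        gap = next(d.value for d in cand.decisions if d.criterion == "arm_gap")
        assert gap > PipelineConfig().arm_gap_max

    def test_missing_flank_fails(self):
        cand = evaluate_candidate(_hairpin_candidate(flank=4))
        failed = {d.criterion for d in cand.decisions if not d.passed}
        assert "flanks" in failed

    def test_unpaired_mature_fails_pairing(self):
        rng = np.random.default_rng(2)
        seq = ("".join(rng.choice(list("ACGT"), 30)) + "A" * 21
               + "".join(rng.choice(list("ACGT"), 30)))
        cand = _mk_candidate(seq, (30, 51))
        cand.fold = fold_mfe(cand.seq)
        cand = evaluate_candidate(cand)
        assert not cand.passed

    def test_decision_trail_is_complete(self):
        cand = evaluate_candidate(_hairpin_candidate())
        assert [d.criterion for d in cand.decisions] == [
            "mature_length", "precursor_mfe", "mature_pairing", "arm_gap", "flanks"
        ]


class TestMipred:
    def test_energy_rule_discards_with_reason(self):
        cand = evaluate_candidate(_hairpin_candidate())
        cfg = PipelineConfig(pseudo_mfe_max=-80.0)  # unreachable cutoff
        keep, reason, p = mipred_filter(cand, 49, 1, cfg)
        assert (keep, reason, p) == (False, "mfe", None)

    def test_pvalue_rule_discards_with_reason(self):
        cand = evaluate_candidate(_hairpin_candidate())
        cfg = PipelineConfig(pseudo_p_max=0.001)  # below 1/(n+1)
        keep, reason, p = mipred_filter(cand, 49, 1, cfg)
        assert (keep, reason) == (False, "pvalue")
        assert p > 0.001

    def test_planted_hairpin_is_kept(self):
        cand = evaluate_candidate(_hairpin_candidate())
        keep, reason, p = mipred_filter(cand, 199, 1, PipelineConfig())
        assert keep and reason is None and p <= 0.05


class TestMatchKnown:
    SAME, FOREIGN = load_toy_references()

    def test_same_species_exact_is_known(self):
        result = match_known("TGAGGTAGGAGGTTGTATAGTT", self.SAME, self.FOREIGN)
        assert (result.status, result.ref_name) == ("known", "ssc-let-7e")

    def test_end_shifted_isomir_collapses_to_known(self):
        result = match_known("AGGTAGGAGGTTGTATAGTT", self.SAME, self.FOREIGN)
        assert result.status == "known"

    def test_foreign_perfect_is_ps(self):
        result = match_known("AGCTGGTGTTGTGAATCAGGCCG", self.SAME, self.FOREIGN)
        assert (result.status, result.ref_name, result.description) == (
            "PS", "mmu-miR-138-5p", "perfect")

    def test_foreign_single_substitution_is_ps_1nt_sub(self):
        query = "AGCTGGTGTTGTGAATCAGGCCG"
        query = query[:5] + "A" + query[6:]  # one substitution
        result = match_known(query, [], self.FOREIGN)
        assert (result.status, result.description) == ("PS", "1nt sub")

    def test_foreign_two_deletions_described(self):
        query = "AGCTGGTGTTGTGAATCAGG"  # 3' truncation of mmu-miR-138-5p
        result = match_known(query, [], self.FOREIGN)
        assert result.status == "PS"
        assert "delete" in result.description

    def test_unrelated_sequence_is_pc(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            query = "".join(rng.choice(list("ACGT"), 22))
            result = match_known(query, self.SAME, self.FOREIGN)
            if result.status == "PC":
                break
        assert result.status == "PC"

    def test_empty_references_rejected(self):
        with pytest.raises(ConfigError):
            match_known("ACGTACGTACGTACGTACGTAC", [], [])


class TestProfile:
    def _profiled(self, reads):
        """Candidate with mature (30,51), star (66,87), loop (51,66)."""
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 120))
        placements = []
        for i, (hs, he, count) in enumerate(reads):
            placements.append((SmallRNATag(f"t{i}", seq[hs:he], count), hs, he))
        cand = _mk_candidate(seq, (30, 51), placements=placements, star=(66, 87))
        cand.mature_tag = placements[0][0]
        return profile_precursor(cand)

    def test_canonical_classes(self):
        profile = self._profiled([
            (30, 51, 100),   # exactly the mature arm -> arm5p
            (66, 87, 10),    # the star arm -> arm3p
            (48, 66, 5),     # 15/18 nt in the inter-arm region -> loop
            (11, 29, 3),     # ends 1 nt before the mature -> moRNA5
            (89, 107, 2),    # starts 2 nt after the star -> moRNA3
            (100, 118, 1),   # far downstream -> other
        ])
        assert profile.counts == {
            "arm5p": 100, "arm3p": 10, "loop": 5,
            "moRNA5": 3, "moRNA3": 2, "other": 1,
        }
        assert profile.dominant_arm == "5p"
        assert profile.coupled

    def test_partial_arm_overlap_is_still_an_arm_read(self):
        profile = self._profiled([(30, 51, 10), (44, 62, 1)])  # 7/18 on the arm
        assert profile.counts["arm5p"] == 11

    def test_single_arm_precursor_is_uncoupled(self):
        profile = self._profiled([(30, 51, 50)])
        assert not profile.coupled
        assert profile.arm_class == "5p"

    def test_read_outside_candidate_is_an_error(self):
        cand = _hairpin_candidate()
        cand.placements.append((SmallRNATag("bad", "A" * 10, 1), -5, 5))
        with pytest.raises(ValueError):
            profile_precursor(cand)

    def test_simulated_classes_recovered(self, small_run):
        from exomir.simulate import score_read_classes

        scores = score_read_classes(
            small_run["provenance"], small_run["result"].tag_classes
        )
        assert scores["accuracy"] >= 0.95


class TestArmAccounting:
    def test_totals_row_is_columnwise_sum(self):
        table = arm_table({
            "known": {"pre_mirnas": 205, "5p": 67, "3p": 57, "both": 33, "mature": 176},
            "novel": {"pre_mirnas": 366, "5p": 150, "3p": 139, "both": 17, "mature": 315},
        })
        assert table.loc["total", "5p"] == 217
        assert table.loc["total", "both"] == 50
        assert table.loc["total", "mature"] == 491
        assert (table.loc["total"] == table.loc["known"] + table.loc["novel"]).all()

    def test_toy_records_one_of_each_arm_class(self, small_run):
        from exomir.discover import arm_accounting

        table = arm_accounting(small_run["result"].records)
        assert (table.loc["total"] == table.loc["known"] + table.loc["novel"]).all()
        n_classes = (table.loc["total", "5p"] + table.loc["total", "3p"]
                     + table.loc["total", "both"])
        assert n_classes == table.loc["total", "mature"]


class TestRecords:
    def test_discovered_matures_all_match_planted(self, small_run):
        truth, result = small_run["truth"], small_run["result"]
        scores = score_discovery(truth, [r.mature for r in result.records])
        assert scores["precision"] == 1.0
        assert scores["recall"] >= 0.9

    def test_copy_groups_collapse_to_single_records(self, small_run):
        truth, result = small_run["truth"], small_run["result"]
        for prec in truth.precursors:
            if prec.copies < 2:
                continue
            matching = [r for r in result.records
                        if match_mature_to_truth(r.mature, truth) == prec.precursor_id]
            assert len(matching) == 1
            assert len(matching[0].loci) == prec.copies

    def test_isomir_mass_is_collapsed_into_the_record(self, small_run):
        truth, result = small_run["truth"], small_run["result"]
        prov = small_run["provenance"]
        for rec in result.records[:3]:
            pid = match_mature_to_truth(rec.mature, truth)
            prec = next(p for p in truth.precursors if p.precursor_id == pid)
            dom_cls = "arm5p" if prec.mature_arm == "5p" else "arm3p"
            planted = len(prov[(prov["source"] == pid) & (prov["class"] == dom_cls)])
            assert rec.count >= 0.9 * planted
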
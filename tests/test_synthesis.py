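"""Cycle planning and orchestration: exact covers, bookkeeping identity,
base-composition concentration, confinement audit."""

import numpy as np
import pytest

from synthchip.addressing import ArrayGeometry, UnitAddress
from synthchip.fixtures import gen_census_fixture, gen_random_oligos
from synthchip.synthesis import (BASES, CycleState, OligoJob,
                                 confinement_audit, cycle_plan, load_jobs,
                                 run_synthesis)

GEOM = ArrayGeometry(n_rows=40, n_cols=40, n_blocks=8, pitch_um=1.0)


def make_job(seqs, geom=GEOM):
    targets = {UnitAddress(i // geom.n_cols, i % geom.n_cols): s
               for i, s in enumerate(seqs)}
    return OligoJob(targets=targets, geometry=geom)


class TestOligoJob:
    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            make_job(["ACGN"])

    def test_rejects_empty_sequence(self):
        with pytest.raises(ValueError, match="empty"):
            make_job([""])

    def test_rejects_out_of_array_site(self):
        with pytest.raises(ValueError, match="outside"):
            OligoJob(targets={UnitAddress(99, 0): "ACGT"}, geometry=GEOM)


class TestLoadJobs(object):
    def test_row_major_and_explicit_sites(self, tmp_path):
        fa = tmp_path / "oligos.fa"
        fa.write_text(
            ">a\nACGT\n>b\nTTTT\n>c site=5,7\nGGCC\n"
        )
        job = load_jobs(fa, GEOM)
        assert job.targets[UnitAddress(0, 0)] == "ACGT"
        assert job.targets[UnitAddress(0, 1)] == "TTTT"
        assert job.targets[UnitAddress(5, 7)] == "GGCC"

    def test_duplicate_site_is_error(self, tmp_path):
        fa = tmp_path / "dup.fa"
        fa.write_text(">a site=1,1\nAC\n>b site=1,1\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_jobs(fa, GEOM)

    def test_non_acgt_record_is_error(self, tmp_path):
        fa = tmp_path / "bad.fa"
        fa.write_text(">a\nACGNACGT\n")
        with pytest.raises(ValueError, match="non-ACGT"):
            load_jobs(fa, GEOM)


class TestCyclePlan:
    def test_masks_partition_next_bases(self):
        job = make_job(["ACG", "CCT", "AAA"])
        masks = cycle_plan(CycleState.fresh(job), job)
        assert masks["A"].sum() == 2
        assert masks["C"].sum() == 1
        assert masks["G"].sum() == 0
        assert masks["T"].sum() == 0

    def test_finished_sites_appear_nowhere(self):
        job = make_job(["AC", "G"])
        state = CycleState.fresh(job)
        state.lengths = {s: len(t) for s, t in job.targets.items()}
        masks = cycle_plan(state, job)
        assert all(masks[b].sum() == 0 for b in BASES)

    def test_masks_disjoint_and_cover_unfinished(self, rng):
        seqs = ["".join(rng.choice(list(BASES), size=rng.integers(1, 9)))
                for _ in range(200)]
        job = make_job(seqs)
        state = CycleState.fresh(job)
        state.lengths = {
            s: int(rng.integers(0, len(t) + 1)) for s, t in job.targets.items()
        }
        masks = cycle_plan(state, job)
        total = np.zeros_like(masks["A"], dtype=int)
        for b in BASES:
            total += masks[b].astype(int)
        assert total.max() <= 1  # pairwise disjoint
        unfinished = {s for s, t in job.targets.items()
                      if state.lengths[s] < len(t)}
        covered = {UnitAddress(int(r), int(c))
                   for r, c in zip(*np.nonzero(total))}
        assert covered == unfinished

    def test_base_masks_concentrate_at_quarter(self):
        """Uniform random sequences activate ~N/4 sites per base (4 sigma),
        the regime behind the chip's 2.5e6-of-1e7 activation estimate."""
        geom = ArrayGeometry(n_rows=320, n_cols=320, n_blocks=32, pitch_um=1.0)
        n = geom.n_units  # 102,400 sites
        fasta = gen_random_oligos(1, 1, seed=5)  # warm the generator API
        rng = np.random.default_rng(5)
        seqs = rng.choice(list(BASES), size=n)
        targets = {
            UnitAddress(i // geom.n_cols, i % geom.n_cols): str(seqs[i])
            for i in range(n)
        }
        job = OligoJob(targets=targets, geometry=geom)
        masks = cycle_plan(CycleState.fresh(job), job)
        sigma = np.sqrt(n * 0.25 * 0.75)
        for b in BASES:
            assert abs(masks[b].sum() - n / 4) < 4 * sigma


class TestRunSynthesis:
    def test_identical_sequences_one_mask_per_cycle(self):
        job = make_job(["ACGT"] * 5)
        report = run_synthesis(job, t_hold_s=1.0)
        assert report.n_cycles == 4
        for counts in report.base_counts:
            assert sum(1 for v in counts.values() if v > 0) == 1

    def test_products_equal_targets(self, rng):
        seqs = ["".join(rng.choice(list(BASES), size=rng.integers(1, 7)))
                for _ in range(50)]
        job = make_job(seqs)
        report = run_synthesis(job, t_hold_s=1.0)
        assert report.products == dict(job.targets)

    def test_cycle_count_is_max_length(self, rng):
        for trial in range(50):
            lens = rng.integers(1, 10, size=8)
            seqs = ["".join(rng.choice(list(BASES), size=k)) for k in lens]
            job = make_job(seqs)
            report = run_synthesis(job, t_hold_s=1.0, collect_products=False)
            assert report.n_cycles == int(lens.max())

    def test_mixed_lengths_idle_after_completion(self):
        job = make_job(["AAAA", "A"])
        report = run_synthesis(job, t_hold_s=1.0)
        # cycle 0 has both sites; cycles 1-3 only the long one
        assert report.base_counts[0]["A"] == 2
        assert all(c["A"] == 1 for c in report.base_counts[1:])

    def test_per_cycle_counts_sum_to_unfinished(self, rng):
        seqs = ["".join(rng.choice(list(BASES), size=rng.integers(1, 6)))
                for _ in range(30)]
        job = make_job(seqs)
        report = run_synthesis(job, t_hold_s=1.0, collect_products=False)
        lens = sorted(len(s) for s in seqs)
        for k, counts in enumerate(report.base_counts):
            unfinished = sum(1 for s in seqs if len(s) > k)
            assert sum(counts.values()) == unfinished


class TestConfinementAudit:
    def setup_method(self):
        self.areas, self.confined = gen_census_fixture(8, 8, seed=3)
        self.active = np.zeros((8, 8), dtype=bool)
        self.active[2, 2] = True

    def test_confined_activation_deprotects_site_only(self):
        out = confinement_audit(self.active, self.areas, self.confined)
        assert out["deprotected"] == {UnitAddress(2, 2)}
        assert out["at_risk"] == set()

    def test_no_droplet_no_reaction(self):
        areas = self.areas.copy()
        areas[2, 2] = 0.0
        confined = self.confined.copy()
        confined[2, 2] = False
        out = confinement_audit(self.active, areas, confined)
        assert out["deprotected"] == set()

    def test_unconfined_mode_flags_four_neighbours(self):
        out = confinement_audit(self.active, self.areas, self.confined,
                                mode="unconfined")
        assert out["at_risk"] == {
            UnitAddress(1, 2), UnitAddress(3, 2),
            UnitAddress(2, 1), UnitAddress(2, 3),
        }

    def test_confined_mode_never_has_at_risk_sites(self, rng):
        """The platform's headline property: with droplets confined, no
        neighbour of any activated site is ever at risk."""
        for _ in range(20):
            active = rng.random((8, 8)) < 0.3
            out = confinement_audit(active, self.areas, self.confined)
            assert out["at_risk"] == set()
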
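"""Generator contracts: composition, determinism, planted-event hallmarks."""

import numpy as np
import pytest

from ervscan.consensus import default_library
from ervscan.simulate import (ConfigError, SimulationConfig, TruthLedger,
                              derive_outgroups, generate_ancestor,
                              plant_element, plant_ncpi, simulate)


def cfg(**kw) -> SimulationConfig:
    base = dict(seed=1, ancestor_length_bp=200_000, n_chromosomes=1,
                n_full_length=0, n_solo_ltr=0, n_truncated=0, n_ncpi=0,
                n_outgroups=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateAncestor:
    def test_deterministic_for_fixed_seed(self):
        a = generate_ancestor(cfg(ancestor_length_bp=10_000, gc_fraction=0.5))
        b = generate_ancestor(cfg(ancestor_length_bp=10_000, gc_fraction=0.5))
        assert a == b
        assert len(a["chr1"]) == 10_000

    def test_seed_sensitivity(self):
        a = generate_ancestor(cfg(seed=1))
        b = generate_ancestor(cfg(seed=2))
        assert a != b

    def test_gc_zero_gives_only_at(self):
        genome = generate_ancestor(cfg(ancestor_length_bp=5_000, gc_fraction=0.0))
        assert set(genome["chr1"]) <= {"A", "T"}

    @pytest.mark.parametrize("gc", [0.3, 0.5, 0.6])
    def test_base_composition_tracks_gc(self, gc):
        genome = generate_ancestor(cfg(ancestor_length_bp=100_000, gc_fraction=gc))
        seq = genome["chr1"]
        observed = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(observed - gc) < 0.02

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ConfigError):
            generate_ancestor(cfg(ancestor_length_bp=0))

    def test_chromosome_lengths_sum(self):
        genome = generate_ancestor(cfg(ancestor_length_bp=100_001,
                                       n_chromosomes=3))
        assert sum(map(len, genome.values())) == 100_001
        assert len(genome) == 3


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(tsd_length_range=(0, 5)), dict(tsd_length_range=(2, 11)),
        dict(n_full_length=-1), dict(ltr_mutation_rate=-0.1),
        dict(gc_fraction=1.5), dict(ncpi_deletion_range_bp=(100, 10)),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            cfg(**bad).validate()


class TestPlantElement:
    def test_full_length_structure(self, library):
        config = cfg()
        genome = generate_ancestor(config)
        rng = np.random.default_rng(0)
        cons = library["CERV1"]
        derived, ev = plant_element(genome, "chr1", 100_000, cons,
                                    "full_length", config, rng, age=0.0)
        seq = derived["chr1"]
        t = len(ev.tsd)
        # TSD duplicated on both sides of the element
        assert seq[ev.start - t:ev.start] == ev.tsd
        assert seq[ev.end:ev.end + t] == ev.tsd
        assert 2 <= t <= 5
        # age 0: the element is the unmutated consensus
        assert seq[ev.start:ev.end] == cons.full_sequence
        assert len(derived["chr1"]) == len(genome["chr1"]) + t + len(cons.full_sequence)

    def test_solo_ltr_record(self, library):
        config = cfg()
        genome = generate_ancestor(config)
        derived, ev = plant_element(genome, "chr1", 50_000, library["CERV2"],
                                    "solo_ltr", config,
                                    np.random.default_rng(1), age=0.0)
        assert ev.category == "solo_ltr"
        assert ev.end - ev.start == library["CERV2"].ltr_length
        assert ev.internal_spans == []

    def test_zero_age_gives_identical_ltrs(self, library):
        config = cfg()
        genome = generate_ancestor(config)
        derived, ev = plant_element(genome, "chr1", 80_000, library["CERV1"],
                                    "full_length", config,
                                    np.random.default_rng(2), age=0.0)
        seq = derived["chr1"]
        ltr5 = seq[ev.ltr5_span[0]:ev.ltr5_span[1]]
        ltr3 = seq[ev.ltr3_span[0]:ev.ltr3_span[1]]
        assert ltr5 == ltr3

    def test_aged_ltrs_diverge(self, library):
        config = cfg()
        genome = generate_ancestor(config)
        derived, ev = plant_element(genome, "chr1", 80_000, library["CERV1"],
                                    "full_length", config,
                                    np.random.default_rng(3), age=10.0)
        seq = derived["chr1"]
        ltr5 = seq[ev.ltr5_span[0]:ev.ltr5_span[1]]
        ltr3 = seq[ev.ltr3_span[0]:ev.ltr3_span[1]]
        assert ltr5 != ltr3


class TestPlantNcpi:
    @staticmethod
    def plant_at_first_clean_site(genome, **kwargs):
        """Direct plant_ncpi calls must resample on chance collisions, as
        the orchestrator does."""
        from ervscan.simulate import PlacementError
        for site in range(100_000, 150_000, 1_000):
            try:
                derived, ev = plant_ncpi(genome, "chr1", site, **kwargs)
                return site, derived, ev
            except PlacementError:
                continue
        raise AssertionError("no clean site found")

    def test_deletion_and_microhomology(self, library):
        config = cfg()
        genome = generate_ancestor(config)
        deletion = 500
        site, derived, ev = self.plant_at_first_clean_site(
            genome, cons=library["CERV1"], config=config,
            rng=np.random.default_rng(4), structure="solo_ltr",
            deletion_size=deletion, microhomology=(3, 2))
        deleted = genome["chr1"][site:site + deletion]
        seq = derived["chr1"]
        assert len(seq) == len(genome["chr1"]) - deletion + (ev.end - ev.start)
        assert ev.tsd is None and ev.deletion_size_bp == deletion
        elem = seq[ev.start:ev.end]
        # junctions share the planted microhomology with the element termini
        assert seq[ev.start - 3:ev.start] == elem[:3] == ev.microhomology_left
        assert seq[ev.end:ev.end + 2] == elem[-2:] == ev.microhomology_right
        # the deleted ancestral segment is gone
        assert deleted not in seq

    def test_zero_deletion_boundary(self, library):
        config = cfg()
        genome = generate_ancestor(config)
        _, derived, ev = self.plant_at_first_clean_site(
            genome, cons=library["CERV2"], config=config,
            rng=np.random.default_rng(5), structure="solo_ltr",
            deletion_size=0, microhomology=(0, 0))
        assert ev.deletion_size_bp == 0
        assert ev.microhomology_left == "" and ev.microhomology_right == ""
        assert len(derived["chr1"]) == len(genome["chr1"]) + (ev.end - ev.start)


class TestDeriveOutgroups:
    def test_zero_divergence_is_identity(self):
        config = cfg(outgroup_divergence=0.0)
        anc = generate_ancestor(config)
        (og,) = derive_outgroups(anc, config, 1)
        assert og == anc

    def test_observed_mismatch_matches_divergence(self):
        config = cfg(ancestor_length_bp=100_000, outgroup_divergence=0.01)
        anc = generate_ancestor(config)
        (og,) = derive_outgroups(anc, config, 1)
        mism = sum(a != b for a, b in zip(anc["chr1"], og["chr1"]))
        assert abs(mism / 100_000 - 0.01) < 0.001

    def test_requires_at_least_one(self):
        config = cfg()
        with pytest.raises(ConfigError):
            derive_outgroups(generate_ancestor(config), config, 0)


class TestSimulateDataset:
    def test_event_count_equals_configured_counts(self, small_dataset):
        config = small_dataset.config
        expected = (config.n_full_length + config.n_solo_ltr
                    + config.n_truncated + config.n_ncpi)
        assert len(small_dataset.ledger.events) == expected
        assert len(small_dataset.ledger.decoys) == config.n_decoy_shared

    def test_ledger_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "truth.json"
        small_dataset.ledger.to_json(path)
        back = TruthLedger.from_json(path)
        assert back.events == small_dataset.ledger.events
        assert back.decoys == small_dataset.ledger.decoys

    def test_ncpi_invariants(self, small_dataset):
        for ev in small_dataset.ledger.events:
            if ev.category == "ncpi":
                assert ev.tsd is None and ev.deletion_size_bp >= 0
            else:
                assert ev.deletion_size_bp == 0 and ev.tsd is not None


class TestRepeatMaskerEmission:
    @staticmethod
    def rows_for(ledger_path_text, event):
        rows = []
        for line in ledger_path_text.splitlines()[3:]:
            fields = line.split()
            if not fields:
                continue
            if int(fields[5]) - 1 >= event.start and int(fields[6]) <= event.end:
                rows.append(fields)
        return rows

    def test_row_counts_by_structure(self, small_dataset, tmp_path):
        from ervscan.simulate import emit_repeatmasker_out
        out = tmp_path / "r.out"
        emit_repeatmasker_out(small_dataset.ledger, small_dataset.ingroup,
                              small_dataset.config, small_dataset.library, out)
        text = out.read_text()
        for ev in small_dataset.ledger.events:
            rows = self.rows_for(text, ev)
            if ev.structure == "full_length":
                assert len(rows) >= 3
            elif ev.structure == "solo_ltr":
                assert len(rows) == 1

    def test_split_mode_splits_internal(self, library):
        config = cfg(n_full_length=1, ancestor_length_bp=300_000,
                     split_internal_fragments=True, split_gap_bp=80)
        dataset = simulate(config)
        from ervscan.simulate import emit_repeatmasker_out
        import io as _io
        ev = dataset.ledger.events[0]
        rows = [r for r in _event_rows_helper(dataset) if r[2].endswith("-int")]
        assert len(rows) == 2
        gap = rows[1][0] - rows[0][1]
        assert 0 < gap <= config.split_gap_bp


def _event_rows_helper(dataset):
    from ervscan.simulate import _event_rows
    ev = dataset.ledger.events[0]
    return _event_rows(ev, dataset.config)


def test_byte_identical_outputs_for_fixed_seed(tmp_path):
    import hashlib

    def digest(d):
        h = hashlib.sha256()
        for p in sorted(d.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
        return h.hexdigest()

    config = dict(seed=9, ancestor_length_bp=300_000, n_full_length=1,
                  n_solo_ltr=1, n_truncated=0, n_ncpi=1, n_outgroups=1)
    simulate(SimulationConfig(**config)).write(tmp_path / "a")
    simulate(SimulationConfig(**config)).write(tmp_path / "b")
    assert digest(tmp_path / "a") == digest(tmp_path / "b")
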
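import numpy as np
import pandas as pd
import pytest

from ilkit.genome import ChromosomeSpec, GeneticMap, Genome, linear_map, uniform_panel
from ilkit.qtl import compare_to_control
from ilkit.segments import IntrogressionSegment
from ilkit.sim import (
    DONOR,
    RECURRENT,
    FleshColorSpec,
    Individual,
    QTLSpec,
    SimulationConfig,
    TraitArchitecture,
    TraitSpec,
    flesh_color,
    genotype_individual,
    make_cross,
    run_breeding_scheme,
    simulate_gamete,
    simulate_phenotypes,
)


def one_chrom_genome(cm: float, bp: int = 10_000_000) -> tuple[Genome, GeneticMap]:
    g = Genome((ChromosomeSpec("c1", bp, cm),))
    return g, linear_map(g)


class TestMeiosis:
    def test_zero_genetic_length_transmits_a_parent_unchanged(self):
        g, m = one_chrom_genome(0.0)
        rec = Individual.founder("R", g, RECURRENT)
        don = Individual.founder("D", g, DONOR)
        f1 = make_cross(rec, don, m, g, np.random.default_rng(0), "F1")
        rng = np.random.default_rng(1)
        picks = []
        for _ in range(2000):
            gam = simulate_gamete(f1, m, g, rng)
            ends, labels = gam.segments["c1"]
            assert len(labels) == 1  # no crossover possible
            picks.append(int(labels[0]))
        assert np.mean(picks) == pytest.approx(0.5, abs=0.03)

    def test_crossover_count_mean_equals_morgans(self):
        # 100 cM chromosome: segments - 1 counts crossovers in an F1 gamete
        g, m = one_chrom_genome(100.0)
        rec = Individual.founder("R", g, RECURRENT)
        don = Individual.founder("D", g, DONOR)
        f1 = make_cross(rec, don, m, g, np.random.default_rng(0), "F1")
        rng = np.random.default_rng(2)
        counts = []
        for _ in range(10_000):
            ends, labels = simulate_gamete(f1, m, g, rng).segments["c1"]
            counts.append(len(labels) - 1)
        assert np.mean(counts) == pytest.approx(1.0, abs=0.04)

    def test_haldane_recombinant_fraction_at_50_cm(self):
        # two loci 50 cM apart: r = (1 - e^-1)/2 = 0.3161
        g, m = one_chrom_genome(50.0, bp=5_000_000)
        rec = Individual.founder("R", g, RECURRENT)
        don = Individual.founder("D", g, DONOR)
        f1 = make_cross(rec, don, m, g, np.random.default_rng(0), "F1")
        rng = np.random.default_rng(3)
        loci = np.array([0, 4_999_999])
        rec_count = 0
        n = 30_000
        for _ in range(n):
            gam = simulate_gamete(f1, m, g, rng)
            a, b = gam.label_at("c1", loci)
            rec_count += int(a != b)
        expected = (1 - np.exp(-1.0)) / 2
        assert rec_count / n == pytest.approx(expected, abs=0.012)

    def test_gamete_tiles_chromosome_without_gaps(self, genome, gmap, founders):
        rec, don = founders
        rng = np.random.default_rng(4)
        f1 = make_cross(rec, don, gmap, genome, rng, "F1")
        bc1 = make_cross(rec, f1, gmap, genome, rng, "b")
        gam = simulate_gamete(bc1, gmap, genome, rng)
        for c in genome.chromosomes:
            ends, labels = gam.segments[c.name]
            assert ends[-1] == c.physical_length
            assert np.all(np.diff(ends) > 0)
            assert np.all(labels[1:] != labels[:-1])  # merged mosaic


class TestCrosses:
    def test_self_of_homozygote_is_genotypically_identical(self, genome, gmap):
        rec = Individual.founder("R", genome, RECURRENT)
        rng = np.random.default_rng(5)
        child = make_cross(rec, None, gmap, genome, rng, "S")
        panel = uniform_panel(genome, 24, gmap)
        assert (genotype_individual(child, panel, genome) == "A").all()

    def test_inbred_cross_is_fully_heterozygous(self, genome, gmap, founders):
        rec, don = founders
        f1 = make_cross(rec, don, gmap, genome, np.random.default_rng(6), "F1")
        panel = uniform_panel(genome, 24, gmap)
        assert (genotype_individual(f1, panel, genome) == "H").all()
        assert f1.generation == "F1"

    def test_backcross_always_carries_a_recurrent_allele(self, genome, gmap, founders):
        rec, don = founders
        rng = np.random.default_rng(7)
        f1 = make_cross(rec, don, gmap, genome, rng, "F1")
        bc1 = make_cross(rec, f1, gmap, genome, rng, "b")
        assert bc1.generation == "BC1"
        for c in genome.chromosomes:
            probes = np.linspace(0, c.physical_length - 1, 200).astype(np.int64)
            assert bc1.dose_at(c.name, probes).max() <= 1

    def test_generation_labels_advance_through_selfing(self, genome, gmap, founders):
        rec, don = founders
        rng = np.random.default_rng(8)
        f1 = make_cross(rec, don, gmap, genome, rng, "F1")
        bc1 = make_cross(rec, f1, gmap, genome, rng, "a")
        bc2 = make_cross(bc1, rec, gmap, genome, rng, "b")
        s1 = make_cross(bc2, None, gmap, genome, rng, "c")
        s2 = make_cross(s1, None, gmap, genome, rng, "d")
        assert (bc2.generation, s1.generation, s2.generation) == ("BC2", "BC2S1", "BC2S2")

    def test_mismatched_genomes_rejected(self, genome, gmap):
        other = Genome((ChromosomeSpec("cX", 1000, 1.0),))
        a = Individual.founder("A", genome, RECURRENT)
        b = Individual.founder("B", other, DONOR)
        with pytest.raises(ValueError, match="genome configurations differ"):
            make_cross(a, b, gmap, genome, np.random.default_rng(0), "x")


class TestGenotyping:
    def test_calls_match_brute_force_haplotype_lookup(self, genome, gmap, founders):
        rec, don = founders
        rng = np.random.default_rng(9)
        f1 = make_cross(rec, don, gmap, genome, rng, "F1")
        ind = make_cross(rec, f1, gmap, genome, rng, "b")
        panel = uniform_panel(genome, 96, gmap)
        calls = genotype_individual(ind, panel, genome)
        for _, row in panel.markers.iterrows():
            # oracle: scan each haplotype's segment list directly
            dose = 0
            for hap in (ind.maternal, ind.paternal):
                ends, labels = hap.segments[row["chrom"]]
                i = int(np.searchsorted(ends, row["bp"], side="right"))
                dose += int(labels[min(i, len(labels) - 1)])
            assert calls[row["marker_id"]] == {0: "A", 1: "H", 2: "B"}[dose]

    def test_zero_missing_rate_has_no_missing_calls(self, genome, gmap, founders):
        rec, _ = founders
        panel = uniform_panel(genome, 48, gmap)
        calls = genotype_individual(rec, panel, genome, missing_rate=0.0)
        assert calls.notna().all()

    def test_missing_rate_masks_calls(self, genome, gmap, founders):
        rec, _ = founders
        panel = uniform_panel(genome, 96, gmap)
        calls = genotype_individual(
            rec, panel, genome, missing_rate=0.3, rng=np.random.default_rng(10)
        )
        frac = calls.isna().mean()
        assert 0.1 < frac < 0.5

    def test_marker_beyond_chromosome_end_rejected(self, genome, founders):
        rec, _ = founders
        df = pd.DataFrame(
            [("m1", "chr01", 10, 0.0), ("m2", "chr01", 40_000_000, 1.0)],
            columns=["marker_id", "chrom", "bp", "cm"],
        )
        panel = GeneticMap(df)
        with pytest.raises(ValueError, match="outside chromosome"):
            genotype_individual(rec, panel, genome)


class TestBreedingScheme:
    def test_same_seed_reproduces_collection_and_stats(self, small_scheme_run, small_config):
        collection, stats = small_scheme_run
        collection2, stats2 = run_breeding_scheme(SimulationConfig(**small_config))
        assert [r.line_id for r in collection] == [r.line_id for r in collection2]
        assert [r.segments for r in collection] == [r.segments for r in collection2]
        pd.testing.assert_frame_equal(stats, stats2)

    def test_final_lines_carry_one_homozygous_segment(self, small_scheme_run):
        collection, _ = small_scheme_run
        assert len(collection) > 0
        for rec in collection:
            assert len(rec.segments) == 1
            assert rec.segments[0].zygosity == "homozygous-donor"

    def test_heterozygosity_decays_through_generations(self, small_scheme_run):
        _, stats = small_scheme_run
        by_gen = stats.set_index("generation")["mean_pct_heterozygous"]
        assert by_gen["BC1"] > by_gen["BC2"] > by_gen["BC3"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_bc1=0)
        with pytest.raises(ValueError):
            SimulationConfig(missing_rate=1.5)


class TestFleshColor:
    @pytest.mark.parametrize(
        "gf,wf,color",
        [
            ("A", "A", "orange"),  # Gf/Gf wf/wf: the recurrent parent
            ("B", "B", "white"),  # gf/gf Wf/Wf: the donor parent
            ("B", "A", "green"),  # double recessive gf/gf wf/wf
            ("H", "B", "orange"),  # any Gf allele dominates
            ("B", "H", "white"),
        ],
    )
    def test_epistatic_lookup(self, gf, wf, color):
        assert flesh_color(gf, wf) == color

    def test_missing_call_is_undetermined(self):
        assert flesh_color(np.nan, "A") == "undetermined"
        assert flesh_color("A", None) == "undetermined"


def toy_architecture(genome, qtls, sd_frac=0.0):
    traits = {}
    for q in qtls:
        traits.setdefault(
            q.trait, TraitSpec(q.trait, 100.0, 100.0 * sd_frac)
        )
    return TraitArchitecture(traits=traits, qtls=list(qtls), flesh_color=None)


class TestPhenotypes:
    def test_no_qtl_zero_noise_returns_control_mean(self, genome):
        arch = TraitArchitecture(
            traits={"FW": TraitSpec("FW", 717.0, 0.0)}, qtls=[], flesh_color=None
        )
        coll = {"IL1": [IntrogressionSegment("chr01", 0, 10_000_000, "homozygous-donor")]}
        tab = simulate_phenotypes(coll, arch, replicates=3, rng=0)
        vals = tab.loc[tab["trait"] == "FW", "value"].astype(float)
        assert (vals == 717.0).all()

    def test_ssc_qtl_reproduces_printed_carrier_mean(self, genome):
        # -34.3% on a control mean of 8.78 degBrix gives 5.77 in the carrier
        arch = TraitArchitecture(
            traits={"SSC": TraitSpec("SSC", 8.78, 0.0)},
            qtls=[QTLSpec("SSC", "chr05", 1_500_000, -34.3)],
            flesh_color=None,
        )
        coll = {
            "carrier": [IntrogressionSegment("chr05", 0, 2_830_000, "homozygous-donor")],
            "other": [IntrogressionSegment("chr01", 0, 2_830_000, "homozygous-donor")],
        }
        tab = simulate_phenotypes(coll, arch, replicates=2, rng=0)
        ssc = tab[tab["trait"] == "SSC"].groupby("line")["value"].mean()
        assert ssc["carrier"] == pytest.approx(5.77, abs=0.005)
        assert ssc["other"] == pytest.approx(8.78)

    def test_heterozygous_segment_silent_under_recessive_default(self, genome):
        arch = toy_architecture(genome, [QTLSpec("T", "chr01", 5_000_000, -50.0)])
        coll = {"het": [IntrogressionSegment("chr01", 0, 10_000_000, "heterozygous")]}
        tab = simulate_phenotypes(coll, arch, replicates=2, rng=0)
        vals = tab[(tab.line == "het") & (tab.trait == "T")]["value"].astype(float)
        assert (vals == 100.0).all()

    def test_additive_dominance_halves_het_effect(self, genome):
        arch = toy_architecture(
            genome, [QTLSpec("T", "chr01", 5_000_000, -50.0, dominance="additive")]
        )
        coll = {"het": [IntrogressionSegment("chr01", 0, 10_000_000, "heterozygous")]}
        tab = simulate_phenotypes(coll, arch, replicates=1, rng=0)
        val = float(tab[(tab.line == "het") & (tab.trait == "T")]["value"].iloc[0])
        assert val == pytest.approx(75.0)

    def test_year_effect_added_to_lines_grown_that_year(self, genome):
        arch = TraitArchitecture(
            traits={"FW": TraitSpec("FW", 700.0, 0.0, year_effects={2019: 50.0})},
            qtls=[],
            flesh_color=None,
        )
        coll = {"IL1": []}
        tab = simulate_phenotypes(coll, arch, replicates=1, line_years={"IL1": 2019}, rng=0)
        il = tab[(tab.line == "IL1") & (tab.trait == "FW")]["value"].astype(float)
        assert (il == 750.0).all()

    def test_replicate_count_below_one_rejected(self, genome):
        arch = toy_architecture(genome, [])
        with pytest.raises(ValueError, match="replicate"):
            simulate_phenotypes({}, arch, replicates=0)

    def test_power_to_flag_carrier_lines(self, genome):
        # one -20% FW QTL, sd 5% of the mean, 6 replicates: the downstream
        # Dunnett scan should flag exactly the carrier in >= 95% of runs
        arch = TraitArchitecture(
            traits={"FW": TraitSpec("FW", 700.0, 35.0)},
            qtls=[QTLSpec("FW", "chr02", 10_000_000, -20.0)],
            flesh_color=None,
        )
        coll = {
            "carrier": [IntrogressionSegment("chr02", 5_000_000, 15_000_000, "homozygous-donor")],
            "bg1": [IntrogressionSegment("chr03", 0, 10_000_000, "homozygous-donor")],
            "bg2": [IntrogressionSegment("chr04", 0, 10_000_000, "homozygous-donor")],
        }
        hits = 0
        false_free = 0
        n_runs = 200
        rng = np.random.default_rng(42)
        for _ in range(n_runs):
            tab = simulate_phenotypes(coll, arch, replicates=6, rng=rng)
            res = compare_to_control(tab, "FW", "Ved")
            flagged = set(res.index[res["p"] < 0.05])
            hits += "carrier" in flagged
            false_free += flagged <= {"carrier"}
        assert hits / n_runs >= 0.95
        assert false_free / n_runs >= 0.80
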
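"""Unit and property tests for the MIR outcome/segregation model."""

import math

import numpy as np
import pytest

from mirkit.model import (
    REPAIR_BRANCHES,
    ClassDistribution,
    DonorClass,
    DonorConfig,
    Layout,
    MultiInvasionJM,
    Pathway,
    PathwayUnavailableError,
    RecombinantClass,
    RepairScenario,
    Segregation,
    Signature,
    classify_recombinant,
    enumerate_outcomes,
    infer_mixture,
    min_signature_fraction,
    predict_with_exclusion,
    resolve_multi_invasion,
)
from mirkit.simulate import gen_cohort


def _jm():
    return MultiInvasionJM(
        invading_end="HOcs", internal_donor="LY", terminal_donor="S2"
    )


class TestResolveMultiInvasion:
    def test_mir1_leaves_two_secondary_dsbs(self, ectopic_config):
        prod = resolve_multi_invasion(
            _jm(), ectopic_config, RepairScenario(pathway=Pathway.MIR1)
        )
        assert prod.secondary_dsb_count == 2
        assert ("LY", "Y") in prod.secondary_dsb_sites
        assert prod.translocation["replaces"] == "S2"

    def test_mir2_allelic_insertion_no_dsb(self, allelic_config):
        scenario = RepairScenario(
            pathway=Pathway.MIR2, displacement_synthesis=True
        )
        prod = resolve_multi_invasion(_jm(), allelic_config, scenario)
        assert prod.secondary_dsb_count == 0
        assert prod.translocation["kind"] == "insertion"
        dist = enumerate_outcomes(allelic_config, scenario)
        assert dist.p_signature(Signature.LYS2_S2) == 1.0

    def test_mir2_short_flank_unavailable(self, ectopic_config):
        scenario = RepairScenario(
            pathway=Pathway.MIR2, displacement_synthesis=True
        )
        assert ectopic_config.flank3_homology_bp == 70
        with pytest.raises(PathwayUnavailableError):
            resolve_multi_invasion(_jm(), ectopic_config, scenario)

    def test_mir2_without_synthesis_unavailable(self):
        with pytest.raises(PathwayUnavailableError):
            RepairScenario(pathway=Pathway.MIR2, displacement_synthesis=False)

    @pytest.mark.parametrize("flank", [500, 1000, "full"])
    def test_mir2_available_at_long_flank(self, flank):
        config = DonorConfig(
            layout=Layout.ECTOPIC_TRANS, flank3_homology_bp=flank
        ) if flank != "full" else DonorConfig(
            layout=Layout.ALLELIC_INTERCHROMOSOMAL
        )
        scenario = RepairScenario(
            pathway=Pathway.MIR2, displacement_synthesis=True
        )
        prod = resolve_multi_invasion(_jm(), config, scenario)
        assert prod.pathway is Pathway.MIR2


class TestEnumerateOutcomes:
    def test_gene_conversion_random_segregation_half_ly(
        self, ectopic_config, gene_conversion_scenario
    ):
        dist = enumerate_outcomes(ectopic_config, gene_conversion_scenario)
        assert dist.p_donor_in([DonorClass.B, DonorClass.D]) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_mir2_only_class_c(self):
        config = DonorConfig(
            layout=Layout.ECTOPIC_TRANS, flank3_homology_bp=1000
        )
        dist = enumerate_outcomes(
            config,
            RepairScenario(pathway=Pathway.MIR2, displacement_synthesis=True),
        )
        assert dist.p_donor_in([DonorClass.C]) == 1.0
        # model-level invariant: no secondary SV, never class A or B
        assert all(cls.sv_class == 0 for cls in dist)
        assert all(
            cls.donor_class not in (DonorClass.A, DonorClass.B)
            for cls in dist
        )

    def test_point_mass_regenerate_ly(self, allelic_config):
        dist = enumerate_outcomes(
            allelic_config,
            RepairScenario(p_internal_repair={"regenerate_LY": 1.0}),
        )
        assert dist.p_signature(Signature.LYS2_LY) == pytest.approx(1.0)

    def test_distribution_normalized(self, ectopic_config):
        rng = np.random.default_rng(7)
        for _ in range(25):
            w = rng.dirichlet(np.ones(len(REPAIR_BRANCHES)))
            scenario = RepairScenario(
                p_internal_repair=dict(zip(REPAIR_BRANCHES, w)),
                p_terminal_retention=float(rng.uniform()),
            )
            dist = enumerate_outcomes(ectopic_config, scenario)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_monte_carlo(self, ectopic_config):
        """Exact enumeration matches a multinomial simulation at n=1e5."""
        scenario = RepairScenario(
            p_internal_repair={
                "gene_conversion_with_initiating_end": 0.6,
                "regenerate_LY": 0.25,
                "BIR_homolog": 0.15,
            },
            p_terminal_retention=0.66,
        )
        dist = enumerate_outcomes(ectopic_config, scenario)
        n = 100_000
        counts = gen_cohort(dist, n, seed=11)
        for cls, p in dist.items():
            se = math.sqrt(n * p * (1 - p))
            assert abs(counts.get(cls, 0) - n * p) <= 3 * se


class TestMinSignatureFraction:
    def test_mir1_only_floor_is_half(self, allelic_config):
        assert min_signature_fraction(
            allelic_config, Signature.LYS2_LY, REPAIR_BRANCHES
        ) == pytest.approx(0.5, abs=1e-12)

    def test_mir1_only_ceiling_is_one(self, allelic_config):
        assert min_signature_fraction(
            allelic_config, Signature.LYS2_LY, REPAIR_BRANCHES, maximize=True
        ) == pytest.approx(1.0, abs=1e-12)

    def test_mir2_only_point_value(self, allelic_config):
        scenario = RepairScenario(
            pathway=Pathway.MIR2, displacement_synthesis=True
        )
        assert min_signature_fraction(
            allelic_config, Signature.LYS2_S2, [], scenario=scenario
        ) == 1.0

    def test_monotone_in_regenerate_ly(self, allelic_config):
        """P(LYS2+LY) is non-decreasing in p(regenerate_LY)."""
        prev = -1.0
        for p in np.linspace(0, 1, 11):
            scenario = RepairScenario(
                p_internal_repair={
                    "regenerate_LY": float(p),
                    "regenerate_S2": float(1 - p),
                }
            )
            frac = enumerate_outcomes(allelic_config, scenario).p_signature(
                Signature.LYS2_LY
            )
            assert frac >= prev - 1e-12
            prev = frac


class TestClassifyRecombinant:
    @pytest.mark.parametrize(
        "ly, s2, svs, expected",
        [
            (True, False, (), "B0"),
            (False, True, ("V:II(Y)",), "C1"),
            (True, True, ("V:II(Y)", "V:II(YS2)"), "D3"),
            (False, False, (), "A0"),
            (False, True, ("V:II(YS2)",), "C2"),
        ],
    )
    def test_presence_table(self, ly, s2, svs, expected):
        assert classify_recombinant(ly, s2, svs).label == expected

    def test_signatures(self):
        assert (
            classify_recombinant(True, False, (), "terminal").signature
            is Signature.LYS2_LY
        )
        assert (
            classify_recombinant(False, True, (), "internal").signature
            is Signature.LYS2_S2
        )
        assert (
            classify_recombinant(False, False, (), "both").signature
            is Signature.DOUBLE_LYS2
        )

    def test_unknown_sv_rejected(self):
        with pytest.raises(ValueError):
            classify_recombinant(True, True, ("V:II(Z)",))


class TestPredictWithExclusion:
    @staticmethod
    def _dist(**labels):
        mapping = {
            "B0": RecombinantClass(DonorClass.B, 0),
            "B1": RecombinantClass(DonorClass.B, 1),
            "C1": RecombinantClass(DonorClass.C, 1),
            "D0": RecombinantClass(DonorClass.D, 0),
            "D1": RecombinantClass(DonorClass.D, 1),
        }
        return ClassDistribution({mapping[k]: v for k, v in labels.items()})

    def test_independent_is_identity(self):
        dist = self._dist(B0=0.2, B1=0.1, C1=0.4, D1=0.3)
        assert predict_with_exclusion(dist, Segregation.RANDOM) == dist

    def test_exclusive_moves_b1_to_b0(self):
        dist = self._dist(B0=0.2, B1=0.1, C1=0.7)
        out = predict_with_exclusion(
            dist, Segregation.EXCLUSIVE_LY_WITH_SV1
        )
        assert out.p(RecombinantClass(DonorClass.B, 1)) == 0.0
        assert out.p(RecombinantClass(DonorClass.B, 0)) == pytest.approx(0.3)

    def test_preserves_donor_marginals_and_mass(self):
        dist = self._dist(B0=0.15, B1=0.05, C1=0.4, D0=0.2, D1=0.2)
        out = predict_with_exclusion(dist, "exclusive_LY_with_SV1")
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
        assert out.marginal_donor() == pytest.approx(dist.marginal_donor())


class TestInferMixture:
    def test_disjoint_support_pure_mir2(self):
        d1 = ClassDistribution({RecombinantClass(DonorClass.B, 0): 1.0})
        d2 = ClassDistribution({RecombinantClass(DonorClass.C, 0): 1.0})
        observed = {RecombinantClass(DonorClass.C, 0): 30}
        w, _, ident = infer_mixture(observed, d1, d2)
        assert w == pytest.approx(0.0, abs=1e-6)
        assert ident

    def test_recovers_even_mixture(self):
        d1 = ClassDistribution({RecombinantClass(DonorClass.B, 0): 1.0})
        d2 = ClassDistribution({RecombinantClass(DonorClass.C, 0): 1.0})
        observed = {
            RecombinantClass(DonorClass.B, 0): 5000,
            RecombinantClass(DonorClass.C, 0): 5000,
        }
        w, _, _ = infer_mixture(observed, d1, d2)
        assert w == pytest.approx(0.5, abs=1e-4)

    def test_unidentifiable_returns_half(self):
        d = ClassDistribution(
            {
                RecombinantClass(DonorClass.B, 0): 0.5,
                RecombinantClass(DonorClass.C, 0): 0.5,
            }
        )
        observed = {RecombinantClass(DonorClass.B, 0): 10}
        w, _, ident = infer_mixture(observed, d, d)
        assert w == 0.5
        assert not ident

    def test_empty_cohort_rejected(self):
        d = ClassDistribution({RecombinantClass(DonorClass.B, 0): 1.0})
        with pytest.raises(ValueError):
            infer_mixture({}, d, d)


class TestTypes:
    def test_allelic_forces_full_flank(self, allelic_config):
        assert allelic_config.flank_is_full

    def test_jm_requires_distinct_donors(self):
        with pytest.raises(ValueError):
            MultiInvasionJM("end", "LY", "LY")

    def test_branch_probs_must_normalize(self):
        with pytest.raises(ValueError):
            RepairScenario(p_internal_repair={"regenerate_LY": 0.7})

    def test_distribution_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            ClassDistribution({RecombinantClass(DonorClass.B, 0): 0.7})
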
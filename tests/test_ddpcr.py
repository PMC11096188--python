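"""Droplet-count quantification: Poisson estimator, pooling, the copy/VAF/MGE chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liquidmrd import ddpcr
from liquidmrd.ddpcr import (
    DropletWellRecord,
    ReplicateSpec,
    SampleType,
    SaturationError,
    Timepoint,
    WellRole,
)


def make_well(fam_only, vic_only, double, empty, replicate_id="R1", assay="A1"):
    return DropletWellRecord(
        patient_id="P1",
        timepoint=Timepoint.PRE_TREATMENT,
        sample_type=SampleType.PLASMA,
        assay_id=assay,
        well_id=f"w{fam_only}_{vic_only}_{double}_{empty}",
        role=WellRole.SAMPLE,
        replicate_id=replicate_id,
        n_fam_only=fam_only,
        n_vic_only=vic_only,
        n_double_pos=double,
        n_empty=empty,
    )


class TestPoissonConcentration:
    @pytest.mark.parametrize(
        "k, n, vd, expected",
        [
            (0, 20000, 0.85, 0.0),
            (100, 20000, 0.85, -math.log(0.995) / 0.00085),  # 5.897 copies/uL
            (19900, 20000, 0.85, -math.log(0.005) / 0.00085),  # near saturation
        ],
    )
    def test_closed_form(self, k, n, vd, expected):
        assert ddpcr.poisson_concentration(k, n, vd) == pytest.approx(expected)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            ddpcr.poisson_concentration(20000, 20000, 0.85)

    @pytest.mark.parametrize("k, n", [(-1, 100), (5, 0), (101, 100)])
    def test_invalid_counts(self, k, n):
        with pytest.raises(ValueError):
            ddpcr.poisson_concentration(k, n, 0.85)

    def test_matches_simulated_occupancy_mean(self):
        """The estimator inverts the occupancy model: the mean of many
        simulated wells at a known concentration recovers that concentration."""
        rng = np.random.default_rng(0)
        conc, n, vd = 5.897, 20000, 0.85
        p = 1 - math.exp(-conc * vd * 1e-3)
        ks = rng.binomial(n, p, size=2000)
        ests = [ddpcr.poisson_concentration(int(k), n, vd) for k in ks]
        assert np.mean(ests) == pytest.approx(conc, rel=0.01)

    def test_low_occupancy_linear_limit(self):
        """For occupancy below 1% the Poisson estimate matches (k/n)/Vd within 1%."""
        for k in (1, 17, 199):
            n = 20000
            est = ddpcr.poisson_concentration(k, n, 0.85)
            linear = (k / n) / 0.00085
            assert est == pytest.approx(linear, rel=0.01)


class TestPooling:
    def test_singleton_identity(self):
        w = make_well(2, 500, 1, 19497)
        assert ddpcr.pool_replicate_wells([w]) == (2, 500, 1, 19497)

    def test_additivity(self):
        wells = [make_well(1, 250, 0, 9749), make_well(1, 250, 1, 9748)]
        assert ddpcr.pool_replicate_wells(wells) == (2, 500, 1, 19497)

    def test_eight_wells_vs_per_well_sum(self):
        wells = [make_well(0, 100, 0, 14900) for _ in range(8)]
        pooled = ddpcr.pool_replicate_wells(wells)
        oracle = tuple(
            sum(getattr(w, f) for w in wells)
            for f in ("n_fam_only", "n_vic_only", "n_double_pos", "n_empty")
        )
        assert pooled == oracle == (0, 800, 0, 119200)

    def test_mixed_replicates_rejected(self):
        wells = [make_well(1, 1, 1, 100, "R1"), make_well(1, 1, 1, 100, "R2")]
        with pytest.raises(ValueError, match="replicate"):
            ddpcr.pool_replicate_wells(wells)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ddpcr.pool_replicate_wells([])


@pytest.mark.parametrize(
    "mut, wt, expected",
    [
        (69.4, 50.0, 69.4 / 119.4),  # re-validated MCF7 concentrations -> 0.5812
        (0.0, 10.0, 0.0),
        (5.0, 0.0, 1.0),
    ],
)
def test_vaf_from_concentrations(mut, wt, expected):
    assert ddpcr.vaf_from_concentrations(mut, wt) == pytest.approx(expected, abs=1e-10)


def test_vaf_undefined_when_both_zero():
    with pytest.raises(ValueError, match="undefined"):
        ddpcr.vaf_from_concentrations(0.0, 0.0)


class TestCopyChain:
    @pytest.mark.parametrize(
        "conc, n_wells, elution, expected",
        [(0.0, 8, 20, 0.0), (0.05, 8, 20, 8.0), (1.0, 1, 20, 20.0)],
    )
    def test_copies_per_eluate(self, conc, n_wells, elution, expected):
        assert ddpcr.copies_per_eluate(conc, n_wells, elution) == pytest.approx(expected)

    def test_copies_per_eluate_needs_wells(self):
        with pytest.raises(ValueError):
            ddpcr.copies_per_eluate(1.0, 0)

    @pytest.mark.parametrize(
        "copies, ml, expected", [(8.0, 20, 0.4), (0.0, 40, 0.0), (14.6, 20, 0.73)]
    )
    def test_copies_per_ml_plasma(self, copies, ml, expected):
        assert ddpcr.copies_per_ml_plasma(copies, ml) == pytest.approx(expected)

    def test_copies_per_ml_plasma_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            ddpcr.copies_per_ml_plasma(1.0, 0.0)

    @given(
        conc=st.floats(0.001, 1000),
        alpha=st.floats(0.01, 100),
        n_wells=st.integers(1, 20),
        ml=st.floats(1, 40),
    )
    @settings(max_examples=50, deadline=None)
    def test_chain_homogeneity(self, conc, alpha, n_wells, ml):
        """Scaling the concentration by alpha scales eluate and per-mL copies by alpha."""
        e1 = ddpcr.copies_per_eluate(conc, n_wells)
        e2 = ddpcr.copies_per_eluate(alpha * conc, n_wells)
        assert e2 == pytest.approx(alpha * e1, rel=1e-9)
        assert ddpcr.copies_per_ml_plasma(e2, ml) == pytest.approx(
            alpha * ddpcr.copies_per_ml_plasma(e1, ml), rel=1e-9
        )


class TestMge:
    @pytest.mark.parametrize(
        "mass, vaf, expected",
        [(10, 0.0, 0.0), (10, 0.01, 10 * 1000 / 3.3 * 0.01), (3.3, 1.0, 1000.0)],
    )
    def test_values(self, mass, vaf, expected):
        assert ddpcr.mge(mass, vaf) == pytest.approx(expected)

    def test_vaf_bounds(self):
        with pytest.raises(ValueError):
            ddpcr.mge(10, 1.5)

    @given(m=st.floats(0, 1000), v=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_bilinear(self, m, v):
        assert ddpcr.mge(m, v) == pytest.approx(m * v * ddpcr.mge(1.0, 1.0), rel=1e-9)


class TestMaxSensitivity:
    @pytest.mark.parametrize(
        "total, floor, expected",
        [(66_667, 2, 2 / 66_667), (2, 2, 1.0), (20_000, 2, 1e-4)],
    )
    def test_values(self, total, floor, expected):
        assert ddpcr.max_sensitivity(total, floor) == pytest.approx(expected, rel=1e-4)

    def test_rejects_zero_input(self):
        with pytest.raises(ValueError):
            ddpcr.max_sensitivity(0.0)


class TestQuantifyReplicate:
    def test_pool_then_estimate_equals_estimate_on_pooled(self):
        wells = [make_well(3, 100, 1, 19896), make_well(2, 110, 0, 19888)]
        q = ddpcr.quantify_replicate(wells)
        fam = sum(w.fam_positive for w in wells)
        tot = sum(w.n_total for w in wells)
        assert q.mutant_conc == pytest.approx(
            ddpcr.poisson_concentration(fam, tot)
        )
        assert q.n_wells == 2

    def test_full_chain_on_spec_material(self):
        spec = ReplicateSpec("R1", material_amount=20.0, cfdna_mass=160.0)
        wells = [make_well(3, 100, 1, 19896), make_well(2, 110, 0, 19888)]
        q = ddpcr.quantify_replicate(wells, spec)
        assert q.mutant_copies_eluate == pytest.approx(q.mutant_conc * 20 * 2)
        assert q.mutant_copies_per_ml == pytest.approx(q.mutant_copies_eluate / 20)
        assert q.mge == pytest.approx(160.0 * 1000 / 3.3 * q.vaf)
        assert 0 < q.max_sensitivity <= 1

    def test_negative_count_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_well(-1, 0, 0, 100)
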
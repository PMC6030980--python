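"""Peak matching, isotope clusters, QC tables, measuring, re-annotation."""

import numpy as np
import pytest

import oracle
from conftest import random_peptide
from speclink import (
    AnnotationSettings,
    CrossLinkedPSM,
    Peptide,
    Spectrum,
    Tolerance,
    annotate,
    generate_fragments,
    match_isotope_cluster,
    measure,
    parse_sequence,
    qc_points,
    reannotate,
    revert,
)

ISOTOPE_SPACING = 1.0033548378


def by_settings(**kwargs):
    defaults = dict(
        tolerance=Tolerance(20.0, "ppm"),
        ion_types=frozenset({"b", "y"}),
        max_fragment_charge=1,
        losses_enabled=False,
    )
    defaults.update(kwargs)
    return AnnotationSettings(**defaults)


def spectrum_of(mzs, intensities=None, **kwargs):
    mzs = np.asarray(mzs, dtype=float)
    if intensities is None:
        intensities = np.full(len(mzs), 100.0)
    return Spectrum(mz=mzs, intensity=np.asarray(intensities, float), **kwargs)


PEPTIDE_PSM = CrossLinkedPSM(peptides=(Peptide("PEPTIDE"),), precursor_charge=2)


class TestMatching:
    def test_empty_spectrum_yields_no_matches(self):
        annotated = annotate(spectrum_of([]), PEPTIDE_PSM, by_settings())
        assert annotated.matches == ()

    def test_exact_peak_matches_with_zero_error(self):
        annotated = annotate(
            spectrum_of([227.10263]), PEPTIDE_PSM,
            by_settings(tolerance=Tolerance(10, "ppm")),
        )
        assert len(annotated.matches) == 1
        m = annotated.matches[0]
        assert m.fragment.series == "b" and m.fragment.index == 2
        assert abs(m.error_ppm) < 0.05  # placement rounded to 5 decimals

    def test_peak_outside_tolerance_not_matched(self):
        annotated = annotate(
            spectrum_of([227.11]), PEPTIDE_PSM,
            by_settings(tolerance=Tolerance(10, "ppm")),
        )
        assert annotated.matches == ()

    def test_closest_peak_wins(self):
        b2 = 227.10263
        annotated = annotate(
            spectrum_of([b2 - 0.002, b2 + 0.0005]), PEPTIDE_PSM,
            by_settings(tolerance=Tolerance(0.01, "Da")),
        )
        b2_matches = [
            m for m in annotated.monoisotopic_matches
            if m.fragment.series == "b" and m.fragment.index == 2
        ]
        assert [m.peak_index for m in b2_matches] == [1]

    def test_one_peak_may_carry_multiple_fragment_labels(self):
        # one peak inside the (wide, Da) window of both b1 and y1
        psm = CrossLinkedPSM(peptides=(Peptide("AG"),), precursor_charge=2)
        settings = by_settings(
            ion_types=frozenset("by"), tolerance=Tolerance(5.0, "Da")
        )
        annotated = annotate(spectrum_of([74.04]), psm, settings)
        assert len(annotated.monoisotopic_matches) > 1
        assert {m.peak_index for m in annotated.monoisotopic_matches} == {0}

    def test_matches_equal_brute_force_matcher(self):
        rng = np.random.default_rng(17)
        settings = by_settings(tolerance=Tolerance(20, "ppm"))
        for _ in range(20):
            seq = random_peptide(rng)
            psm = CrossLinkedPSM(peptides=(Peptide(seq),), precursor_charge=2)
            frags = generate_fragments(psm, settings)
            planted = [f.mz * (1 + rng.normal(0, 5e-6)) for f in frags]
            noise = rng.uniform(100, 1800, 40).tolist()
            mzs = np.array(sorted(planted + noise))
            annotated = annotate(spectrum_of(mzs), psm, settings)
            got = {
                (annotated.fragments.index(m.fragment), m.peak_index)
                for m in annotated.monoisotopic_matches
            }
            expected = oracle.brute_force_match(mzs, [f.mz for f in frags], 20.0)
            assert got == expected

    def test_enlarging_tolerance_never_removes_matches(self):
        rng = np.random.default_rng(23)
        seq = random_peptide(rng)
        psm = CrossLinkedPSM(peptides=(Peptide(seq),), precursor_charge=2)
        mzs = np.sort(rng.uniform(100, 1500, 200))
        keys_by_tol = []
        for tol in (5.0, 20.0, 80.0):
            annotated = annotate(
                spectrum_of(mzs), psm, by_settings(tolerance=Tolerance(tol, "ppm"))
            )
            keys_by_tol.append(
                {
                    (m.fragment.series, m.fragment.index, m.fragment.charge)
                    for m in annotated.monoisotopic_matches
                }
            )
        assert keys_by_tol[0] <= keys_by_tol[1] <= keys_by_tol[2]

    def test_uniform_ppm_shift_shifts_all_errors_equally(self):
        settings = by_settings(tolerance=Tolerance(50, "ppm"))
        psm = PEPTIDE_PSM
        frags = generate_fragments(psm, settings)
        mzs = np.array(sorted(f.mz for f in frags))
        base = annotate(spectrum_of(mzs), psm, settings)
        shift = 10.0  # ppm
        shifted = annotate(spectrum_of(mzs * (1 + shift * 1e-6)), psm, settings)
        base_err = {
            (m.fragment.series, m.fragment.index): m.error_ppm
            for m in base.monoisotopic_matches
        }
        for m in shifted.monoisotopic_matches:
            key = (m.fragment.series, m.fragment.index)
            assert m.error_ppm - base_err[key] == pytest.approx(
                shift, rel=1e-6, abs=1e-6
            )

    def test_error_units_are_consistent(self):
        rng = np.random.default_rng(2)
        seq = random_peptide(rng)
        psm = CrossLinkedPSM(peptides=(Peptide(seq),), precursor_charge=2)
        settings = by_settings(tolerance=Tolerance(30, "ppm"))
        frags = generate_fragments(psm, settings)
        mzs = np.array(sorted(f.mz * (1 + rng.normal(0, 1e-5)) for f in frags))
        annotated = annotate(spectrum_of(mzs), psm, settings)
        assert annotated.matches
        for m in annotated.monoisotopic_matches:
            assert m.error_ppm == pytest.approx(
                m.error_da / m.fragment.mz * 1e6, rel=1e-9
            )
            assert abs(m.error_da) <= settings.tolerance.window_da(m.fragment.mz)


class TestIsotopeClusters:
    def test_cluster_of_two_at_charge_two(self):
        # planted at fragment m/z and +spacing/2
        settings = by_settings(
            ion_types=frozenset("y"), max_fragment_charge=2,
            tolerance=Tolerance(10, "ppm"),
        )
        psm = CrossLinkedPSM(peptides=(Peptide("PEPTIDEK"),), precursor_charge=2)
        frag = [
            f for f in generate_fragments(psm, settings)
            if f.series == "y" and f.index == 3 and f.charge == 2
        ][0]
        mzs = [frag.mz, frag.mz + ISOTOPE_SPACING / 2]
        annotated = annotate(spectrum_of(mzs), psm, settings)
        cluster = [m for m in annotated.matches if m.fragment == frag]
        assert [m.isotope_peak for m in sorted(cluster, key=lambda m: m.isotope_peak)] == [0, 1]

    def test_gap_stops_extension(self):
        settings = by_settings(tolerance=Tolerance(10, "ppm"))
        psm = PEPTIDE_PSM
        frag = [f for f in generate_fragments(psm, settings)
                if f.series == "b" and f.index == 2][0]
        # peaks at +1 and +3 spacings: cluster stops after k=1
        mzs = [frag.mz, frag.mz + ISOTOPE_SPACING, frag.mz + 3 * ISOTOPE_SPACING]
        annotated = annotate(spectrum_of(mzs), psm, settings)
        cluster = [m for m in annotated.matches if m.fragment == frag]
        assert sorted(m.isotope_peak for m in cluster) == [0, 1]

    def test_no_neighbor_gives_single_peak_cluster(self):
        settings = by_settings(tolerance=Tolerance(10, "ppm"))
        annotated = annotate(spectrum_of([227.10263]), PEPTIDE_PSM, settings)
        assert all(m.isotope_peak == 0 for m in annotated.matches)

    def test_cluster_capped_at_six_isotopes(self):
        settings = by_settings(tolerance=Tolerance(10, "ppm"))
        psm = PEPTIDE_PSM
        frag = [f for f in generate_fragments(psm, settings)
                if f.series == "b" and f.index == 2][0]
        mzs = [frag.mz + k * ISOTOPE_SPACING for k in range(10)]
        annotated = annotate(spectrum_of(mzs), psm, settings)
        cluster = [m for m in annotated.matches if m.fragment == frag]
        assert max(m.isotope_peak for m in cluster) == 6

    def test_extension_requires_monoisotopic_match(self):
        from dataclasses import replace

        settings = by_settings()
        annotated = annotate(spectrum_of([227.10263]), PEPTIDE_PSM, settings)
        non_mono = replace(annotated.matches[0], isotope_peak=1)
        with pytest.raises(ValueError):
            match_isotope_cluster(annotated.spectrum, non_mono, settings)


class TestQcPoints:
    def test_signed_ppm_error(self):
        settings = by_settings(tolerance=Tolerance(20, "ppm"))
        psm = CrossLinkedPSM(peptides=(Peptide("GG"),), precursor_charge=2)
        frag = generate_fragments(psm, settings)[0]
        observed = frag.mz * (1 + 10e-6)
        annotated = annotate(spectrum_of([observed], [55.0]), psm, settings)
        (point,) = qc_points(annotated, axis="intensity")
        assert point.error_ppm == pytest.approx(10.0, abs=1e-6)
        assert point.x == 55.0

    def test_absolute_mode_and_mz_axis(self):
        settings = by_settings(tolerance=Tolerance(20, "ppm"))
        psm = CrossLinkedPSM(peptides=(Peptide("GG"),), precursor_charge=2)
        frag = generate_fragments(psm, settings)[0]
        observed = frag.mz * (1 - 10e-6)
        annotated = annotate(spectrum_of([observed]), psm, settings)
        (signed,) = qc_points(annotated, axis="mz")
        (absolute,) = qc_points(annotated, axis="mz", absolute=True)
        assert signed.error_ppm == pytest.approx(-10.0, abs=1e-6)
        assert absolute.error_ppm == pytest.approx(10.0, abs=1e-6)
        assert signed.x == pytest.approx(observed, rel=1e-12)

    def test_no_matches_give_empty_points(self):
        annotated = annotate(spectrum_of([]), PEPTIDE_PSM, by_settings())
        assert qc_points(annotated) == []

    def test_invalid_axis_rejected(self):
        annotated = annotate(spectrum_of([]), PEPTIDE_PSM, by_settings())
        with pytest.raises(ValueError):
            qc_points(annotated, axis="charge")


class TestMeasure:
    def test_glycine_gap_at_charge_one(self):
        spec = spectrum_of([200.0, 257.02146])
        results = measure(spec, 0, 1, max_charge=1, tolerance=Tolerance(0.005, "Da"))
        assert results[0].mass_delta == pytest.approx(57.02146, abs=1e-5)
        assert results[0].residue_matches == ("G",)

    def test_glycine_gap_at_charge_two(self):
        spec = spectrum_of([200.0, 228.51073])
        results = measure(spec, 0, 1, max_charge=2, tolerance=Tolerance(0.005, "Da"))
        by_charge = {r.charge: r for r in results}
        assert by_charge[2].mass_delta == pytest.approx(57.02146, abs=1e-5)
        assert by_charge[2].residue_matches == ("G",)
        assert by_charge[1].residue_matches == ()

    def test_same_peak_twice_gives_zero_and_no_matches(self):
        spec = spectrum_of([200.0, 300.0])
        for r in measure(spec, 1, 1, max_charge=3):
            assert r.mass_delta == 0.0 and r.residue_matches == ()

    def test_leucine_isoleucine_ambiguity_reported(self):
        spec = spectrum_of([200.0, 313.08406])
        (r,) = measure(spec, 0, 1, max_charge=1, tolerance=Tolerance(0.005, "Da"))
        assert set(r.residue_matches) == {"I", "L"}

    def test_out_of_range_peak_index_rejected(self):
        with pytest.raises(IndexError):
            measure(spectrum_of([200.0]), 0, 5)


class TestReannotate:
    def test_identical_inputs_reproduce_annotation(self):
        settings = by_settings()
        spec = spectrum_of([227.10263, 148.06043])
        original = annotate(spec, PEPTIDE_PSM, settings)
        again = reannotate(original, psm=PEPTIDE_PSM, settings=settings)
        assert again.matches == original.matches

    def test_moving_modification_changes_only_separating_fragments(self, registry):
        settings = by_settings(tolerance=Tolerance(10, "ppm"))
        pep3, _ = parse_sequence("PEMoxTKMDE", registry)
        pep5, _ = parse_sequence("PEMTKMoxDE", registry)
        psm3 = CrossLinkedPSM(peptides=(pep3,), precursor_charge=2)
        psm5 = CrossLinkedPSM(peptides=(pep5,), precursor_charge=2)
        f3 = {(f.series, f.index): f.mz for f in generate_fragments(psm3, settings)}
        f5 = {(f.series, f.index): f.mz for f in generate_fragments(psm5, settings)}
        for key in f3:
            series, index = key
            # fragments whose residue range separates positions 3 and 6
            separates = (
                (series == "b" and 3 <= index < 6)
                or (series == "y" and 3 <= len(pep3) - index < 6)
            )
            if separates:
                assert f3[key] != pytest.approx(f5[key], abs=1e-6)
            else:
                assert f3[key] == pytest.approx(f5[key], abs=1e-9)

    def test_revert_restores_first_annotation_after_chain(self, registry):
        settings = by_settings()
        spec = spectrum_of([227.10263, 148.06043])
        original = annotate(spec, PEPTIDE_PSM, settings)
        pep2, _ = parse_sequence("PEPTIDEK", registry)
        step1 = reannotate(original, psm=CrossLinkedPSM(peptides=(pep2,), precursor_charge=2))
        step2 = reannotate(step1, settings=by_settings(tolerance=Tolerance(0.3, "Da")))
        reverted = revert(step2)
        assert reverted.matches == original.matches
        assert reverted.psm == original.psm
        assert reverted.settings == original.settings
        # the original object was never mutated
        assert original.psm.peptides[0].sequence == "PEPTIDE"

    def test_failed_reparse_leaves_original_untouched(self, registry):
        original = annotate(spectrum_of([227.10263]), PEPTIDE_PSM, by_settings())
        with pytest.raises(Exception):
            parse_sequence("PEPT1DE", registry)
        assert original.psm.peptides[0].sequence == "PEPTIDE"
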
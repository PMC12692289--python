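"""Annotation ingestion and the staged multi-criteria filter."""

import numpy as np
import pytest

from umamipep import (
    AnnotationRecord,
    FilterCriteria,
    apply_filters,
    load_annotations,
    load_docking_sensory_fixture,
    load_published_annotations,
    merge_annotations,
    summarize_stages,
    umami_residue_fraction,
)
from umamipep.screening import ScreeningError


def naive_filter(peptide, fraction, record, c):
    """Direct boolean expression per row — the independent oracle."""
    gt = (lambda v, t: v is not None and v > t) if c.strict else (
        lambda v, t: v is not None and v >= t)
    ok_tox = (not c.require_nontoxic) or (record is not None and record.toxicity == "Non")
    ok_alg = (not c.require_nonallergen) or (record is not None and record.allergen == "Non")
    ok_umami = gt(fraction, c.min_umami_fraction)
    ok_sol = record is not None and gt(record.log_solubility, c.min_log_solubility)
    phys = ok_tox and ok_alg and ok_umami and ok_sol
    docked = phys and record is not None and not record.docking_failed and (
        record.ce is not None and record.cie is not None)
    dock = docked and gt(record.ce, c.min_ce) and gt(record.cie, c.min_cie)
    sens = dock and record is not None and gt(record.sensory_umami, c.min_sensory)
    return phys, docked, dock, sens


def random_annotations(n, seed):
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    records, peptides = [], []
    seen = set()
    while len(peptides) < n:
        pep = "".join(rng.choice(alphabet, size=int(rng.integers(2, 5))))
        if pep in seen:
            continue
        seen.add(pep)
        peptides.append(pep)
        failed = bool(rng.random() < 0.2)
        records.append(AnnotationRecord(
            peptide=pep,
            toxicity="Toxin" if rng.random() < 0.1 else "Non",
            allergen="Allergen" if rng.random() < 0.2 else "Non",
            log_solubility=float(rng.normal(1.0, 1.5)) if rng.random() < 0.9 else None,
            ce=None if failed else float(rng.normal(40, 3)),
            cie=None if failed else float(rng.normal(38, 3)),
            docking_failed=failed,
            sensory_umami=float(rng.uniform(0, 10)) if rng.random() < 0.7 else None,
        ))
    return peptides, records


class TestLoadAnnotations:
    def test_shipped_screening_table_has_82_records(self):
        records = load_published_annotations()
        assert len(records) == 82
        assert sum(r.allergen == "Allergen" for r in records) == 17
        assert all(r.toxicity == "Non" for r in records)
        assert sum(r.log_solubility < 0 for r in records) == 7

    def test_missing_docking_columns_recorded_absent(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("peptide\ttoxicity\tallergen\tlog_s\nVY\tNon\tNon\t0.25\n")
        (rec,) = load_annotations(p)
        assert rec.ce is None and rec.cie is None and rec.sensory_umami is None

    def test_duplicate_peptide_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("peptide\tlog_s\nVY\t0.2\nVY\t0.3\n")
        with pytest.raises(ScreeningError, match="duplicate"):
            load_annotations(p)

    def test_unparseable_numeric_reports_row(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("peptide\tlog_s\nVY\t0.2\nVN\toops\n")
        with pytest.raises(ScreeningError, match="row 3"):
            load_annotations(p)

    def test_energies_with_docking_failed_rejected(self):
        with pytest.raises(ScreeningError, match="docking_failed"):
            AnnotationRecord(peptide="VY", ce=42.0, docking_failed=True)


class TestApplyFilters:
    def fractions(self, peptides):
        return {p: umami_residue_fraction(p) for p in peptides}

    def test_empty_input(self):
        report = apply_filters([], {}, [])
        assert len(report.table) == 0
        assert summarize_stages(report)["physchem_pass"] == 0

    def test_toy_six_peptides_hand_enumerated(self):
        # 2 toxic, 1 allergen, 1 poorly soluble, 2 clean -> physchem-pass 2
        ann = [
            AnnotationRecord(peptide="VD", toxicity="Toxin", allergen="Non", log_solubility=1.0),
            AnnotationRecord(peptide="VE", toxicity="Toxin", allergen="Non", log_solubility=1.0),
            AnnotationRecord(peptide="AG", toxicity="Non", allergen="Allergen", log_solubility=1.0),
            AnnotationRecord(peptide="ST", toxicity="Non", allergen="Non", log_solubility=-0.5),
            AnnotationRecord(peptide="VY", toxicity="Non", allergen="Non", log_solubility=0.3),
            AnnotationRecord(peptide="HG", toxicity="Non", allergen="Non", log_solubility=1.2),
        ]
        peptides = [r.peptide for r in ann]
        report = apply_filters(peptides, self.fractions(peptides), ann)
        summary = summarize_stages(report)
        assert summary["physchem_pass"] == 2
        assert sorted(report.table[report.table["physchem_pass"]]["peptide"]) == ["HG", "VY"]

    def test_missing_physchem_record_rejected(self):
        with pytest.raises(ScreeningError, match="physchem"):
            apply_filters(["VY"], {}, [])

    def test_unannotated_fails_closed_and_is_flagged(self):
        report = apply_filters(["VY"], {"VY": 100.0}, [])
        row = report.table.iloc[0]
        assert not row["physchem_pass"] and row["unannotated"]

    def test_strict_threshold_fails_at_equality(self):
        ann = [AnnotationRecord(peptide="VY", toxicity="Non", allergen="Non",
                                log_solubility=0.5, ce=40.0, cie=45.0)]
        strict = apply_filters(["VY"], {"VY": 100.0}, ann)
        assert not strict.table.iloc[0]["docking_pass"]
        loose = apply_filters(["VY"], {"VY": 100.0}, ann,
                              FilterCriteria(strict=False))
        assert loose.table.iloc[0]["docking_pass"]

    def test_order_independence(self):
        peptides, records = random_annotations(50, seed=3)
        fr = self.fractions(peptides)
        fwd = apply_filters(peptides, fr, records).table
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(peptides))
        rev = apply_filters(perm, fr, records[::-1]).table
        assert fwd.reset_index(drop=True).equals(rev.reset_index(drop=True))

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_naive_row_oracle(self, seed):
        peptides, records = random_annotations(200, seed)
        fr = self.fractions(peptides)
        report = apply_filters(peptides, fr, records)
        by_pep = {r.peptide: r for r in records}
        t = report.table.set_index("peptide")
        for p in peptides:
            expected = naive_filter(p, fr[p], by_pep.get(p), report.criteria)
            got = tuple(bool(t.loc[p, col]) for col in
                        ("physchem_pass", "docked", "docking_pass", "sensory_pass"))
            assert got == expected, p

    @pytest.mark.parametrize("field,tighter", [
        ("min_log_solubility", 1.0), ("min_ce", 42.0),
        ("min_cie", 42.0), ("min_sensory", 7.0), ("min_umami_fraction", 50.0)])
    def test_tightening_thresholds_never_increases_counts(self, field, tighter):
        peptides, records = random_annotations(150, seed=11)
        fr = self.fractions(peptides)
        base = summarize_stages(apply_filters(peptides, fr, records))
        tight = summarize_stages(apply_filters(
            peptides, fr, records, FilterCriteria(**{field: tighter})))
        for stage in ("physchem_pass", "docking_pass", "sensory_pass"):
            assert tight[stage] <= base[stage]

    def test_stage_flags_are_monotone(self):
        peptides, records = random_annotations(100, seed=5)
        t = apply_filters(peptides, self.fractions(peptides), records).table
        assert (~t["docked"] | t["physchem_pass"]).all()
        assert (~t["docking_pass"] | t["docked"]).all()
        assert (~t["sensory_pass"] | t["docking_pass"]).all()


class TestStagedNarrowing:
    def test_reported_pattern_fixture_reproduces_stage_counts(self):
        """82 candidates narrow to 47 physchem-passers, 35 docked, 9 dual
        high-energy candidates and 6 sensory winners under the shipped
        screening table plus the synthetic docking/sensory pattern."""
        base = load_published_annotations()
        annotations = merge_annotations(base, load_docking_sensory_fixture())
        peptides = [r.peptide for r in base]
        fr = {p: umami_residue_fraction(p) for p in peptides}
        summary = summarize_stages(apply_filters(peptides, fr, annotations))
        assert summary["input"] == 82
        assert summary["physchem_pass"] == 47
        assert summary["docked"] == 35
        assert summary["docking_pass"] == 9
        assert summary["sensory_pass"] == 6
        assert summary["docking_pass_peptides"] == [
            "HN", "IS", "IT", "SL", "SM", "SN", "VM", "VN", "VY"]
        assert summary["sensory_pass_peptides"] == ["IS", "SL", "SN", "VM", "VN", "VY"]
        assert len(summary["failed_docking"]) == 9
        assert len(summary["excluded_by"]["nonallergen"]) == 17
        assert summary["excluded_by"]["nontoxic"] == []

    def test_three_rows_at_41_pass_docking(self):
        ann = [AnnotationRecord(peptide=p, toxicity="Non", allergen="Non",
                                log_solubility=1.0, ce=41.0, cie=41.0)
               for p in ("VY", "SG", "HG")] + [
            AnnotationRecord(peptide="AG", toxicity="Non", allergen="Non",
                             log_solubility=1.0, ce=39.0, cie=41.0)]
        peptides = [r.peptide for r in ann]
        fr = {p: umami_residue_fraction(p) for p in peptides}
        assert summarize_stages(apply_filters(peptides, fr, ann))["docking_pass"] == 3

    def test_no_docking_data_means_no_docked_stage(self):
        ann = [AnnotationRecord(peptide="VY", toxicity="Non", allergen="Non",
                                log_solubility=1.0)]
        report = apply_filters(["VY"], {"VY": 100.0}, ann)
        summary = summarize_stages(report)
        assert summary["physchem_pass"] == 1 and summary["docked"] == 0
        assert report.table.iloc[0]["docking_unannotated"]
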
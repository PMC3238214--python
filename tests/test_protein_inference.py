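"""PSM filtering, greedy vs parsimony assignment, FDR."""

import itertools
import math
import random

import pytest

from flourmap import (
    IncidenceMap,
    PeptideObservation,
    ProteinRecord,
    PsmFilterConfig,
    SequenceDatabase,
    estimate_fdr,
    filter_evidence,
    greedy_assign,
    infer_spots,
    parsimony_assign,
)


def make_incidence(spot, mapping):
    peptides = {pep: frozenset(ids) for pep, ids in mapping.items()}
    return IncidenceMap(spot, peptides, {p: 1 for p in peptides})


def obs(seq, ppm=0.0, prob=0.99, spot="s"):
    return PeptideObservation(spot, "trypsin", seq, 1, ppm, prob)


# --- independent oracle: exhaustive minimal-cover search --------------------

def oracle_min_cover(mapping, cultivar=frozenset()):
    """Brute force over all protein subsets; the preference-minimal cover."""
    proteins = sorted({pid for ids in mapping.values() for pid in ids})
    mappable = {p for p, ids in mapping.items() if ids}
    best_key, best = None, None
    for r in range(len(proteins) + 1):
        for subset in itertools.combinations(proteins, r):
            covered = {p for p in mappable if mapping[p] & set(subset)}
            if covered != mappable:
                continue
            n_cult = sum(1 for pid in subset if pid in cultivar)
            n_uniq = sum(
                1 for p, ids in mapping.items()
                if len(ids) == 1 and next(iter(ids)) in subset
            )
            key = (len(subset), -n_cult, -n_uniq, subset)
            if best_key is None or key < best_key:
                best_key, best = key, set(subset)
        if best is not None:
            break
    return best


def random_instance(rng, max_proteins=12, max_peptides=40):
    n_prot = rng.randint(1, max_proteins)
    n_pep = rng.randint(1, max_peptides)
    proteins = [f"P{i:02d}" for i in range(n_prot)]
    mapping = {}
    for j in range(n_pep):
        k = rng.choices([0, 1, 2, 3], weights=[1, 6, 3, 1])[0]
        mapping[f"pep{j:02d}"] = frozenset(rng.sample(proteins, min(k, n_prot)))
    return mapping


class TestFilter:
    def test_thresholds_exact_wording(self, toy_db):
        from flourmap import build_incidence

        pep = "LQLQPFPQPQLSY"
        rows = [
            obs(pep, ppm=100.0, prob=0.99),   # kept: ppm bound inclusive
            obs("QPQPFRPQQPY", ppm=120.0),    # dropped: over 100 ppm
            obs("VRVPVPQL", prob=0.90),       # dropped: probability not > 0.90
        ]
        inc = build_incidence(rows, toy_db)
        out = filter_evidence(rows, inc, PsmFilterConfig(min_peptides=1))
        assert set(out.peptides) == {pep}

    def test_min_peptides_prunes_proteins(self):
        inc = make_incidence("s", {
            "p1": {"A"}, "p2": {"A"}, "p3": {"B"},
        })
        rows = [obs(p) for p in inc.peptides]
        out = filter_evidence(rows, inc, PsmFilterConfig())
        assert out.peptides["p1"] == frozenset({"A"})
        assert out.peptides["p3"] == frozenset()  # B had a single peptide

    def test_idempotent(self):
        inc = make_incidence("s", {
            "p1": {"A"}, "p2": {"A", "B"}, "p3": {"B"}, "p4": {"C"},
        })
        rows = [obs(p) for p in inc.peptides]
        once = filter_evidence(rows, inc, PsmFilterConfig())
        twice = filter_evidence(rows, once, PsmFilterConfig())
        assert once.peptides == twice.peptides


class TestGreedy:
    def test_spot125_credits_16_to_dominant(self, spot125_incidence):
        res = greedy_assign(spot125_incidence)
        assert res.credited_counts["A"] == 16
        assert res.credited_counts["B"] == 5
        assert res.accepted == ["A", "B"]
        assert res.predominant == "A"

    def test_disjoint_proteins_keep_their_peptides(self):
        inc = make_incidence("s", {"p1": {"A"}, "p2": {"A"}, "p3": {"B"}})
        res = greedy_assign(inc)
        assert res.credited_counts == {"A": 2, "B": 1}

    def test_tie_breaks_lexicographic(self):
        inc = make_incidence("s", {"p1": {"A", "B"}, "p2": {"A", "B"}})
        res = greedy_assign(inc)
        assert res.accepted == ["A"]
        assert res.credited_counts == {"A": 2}

    def test_credit_total_equals_mappable_peptides(self):
        rng = random.Random(31)
        for _ in range(50):
            mapping = random_instance(rng)
            inc = make_incidence("s", mapping)
            res = greedy_assign(inc)
            n_mappable = sum(1 for ids in mapping.values() if ids)
            assert sum(res.credited_counts.values()) == n_mappable


class TestParsimony:
    def test_subsumed_protein_rejected(self):
        inc = make_incidence("s", {
            "p1": {"A"}, "p2": {"A"}, "p3": {"A", "B"},
        })
        res = parsimony_assign(inc)
        assert res.accepted == ["A"]

    def test_single_protein_beats_two_partial(self):
        inc = make_incidence("s", {
            "p1": {"A", "C"}, "p2": {"A", "C"}, "p3": {"A", "B", "C"},
            "p4": {"B", "C"}, "p5": {"B", "C"},
        })
        res = parsimony_assign(inc)
        assert res.accepted == ["C"]

    def test_spot125_both_accepted_shared_flagged(self, spot125_incidence):
        res = parsimony_assign(spot125_incidence)
        assert set(res.accepted) == {"A", "B"}
        uniq = res.unique_credited(spot125_incidence)
        assert uniq == {"A": 12, "B": 5}
        assert set(res.ambiguous) == {f"shared_{i:02d}" for i in range(4)}
        # shared peptides go to the preference-first protein owning uniques
        assert all(res.assignment[p] == "A" for p in res.ambiguous)

    def test_cultivar_preference_breaks_ties(self):
        inc = make_incidence("s", {"p1": {"A", "B"}, "p2": {"A", "B"}})
        res = parsimony_assign(inc, cultivar_specific={"B"})
        assert res.accepted == ["B"]

    def test_indistinguishable_group_reported(self):
        inc = make_incidence("s", {"p1": {"A", "B"}, "p2": {"A", "B"}})
        res = parsimony_assign(inc)
        assert res.indistinguishable_groups == [frozenset({"A", "B"})]

    def test_matches_bruteforce_oracle(self):
        rng = random.Random(101)
        for _ in range(150):
            mapping = random_instance(rng)
            cultivar = frozenset(
                pid for ids in mapping.values() for pid in ids
                if rng.random() < 0.3
            )
            inc = make_incidence("s", mapping)
            res = parsimony_assign(inc, cultivar_specific=cultivar)
            assert set(res.accepted) == oracle_min_cover(mapping, cultivar)

    def test_never_larger_than_greedy(self):
        rng = random.Random(77)
        for _ in range(100):
            inc = make_incidence("s", random_instance(rng))
            assert len(parsimony_assign(inc).accepted) <= len(
                greedy_assign(inc).accepted
            )


class TestInferSpots:
    def _db_two_homologs(self):
        shared = "QPQQPFPQQPYPQQSF"
        return SequenceDatabase([
            ProteinRecord(id="H1", sequence=shared + "KDSTWHEVNR",
                          cultivar_specific=True),
            ProteinRecord(id="H2", sequence=shared + "KGCMYESNQV",
                          cultivar_specific=True),
        ])

    def test_per_spot_keeps_spot_specific_homologs(self):
        db = self._db_two_homologs()
        # spot 1 carries H1-unique evidence, spot 2 carries H2-unique;
        # both share the repeat peptides
        ev = {
            "s1": [obs("QPQQPFPQQ", spot="s1"), obs("DSTWHEVNR", spot="s1"),
                   obs("PQQPYPQQSF", spot="s1")],
            "s2": [obs("QPQQPFPQQ", spot="s2"), obs("GCMYESNQV", spot="s2"),
                   obs("PQQPYPQQSF", spot="s2")],
        }
        per = infer_spots(ev, db, mode="parsimony", scope="per_spot",
                          filter_config=PsmFilterConfig(min_peptides=1))
        assert per["results"]["s1"].accepted == ["H1"]
        assert per["results"]["s2"].accepted == ["H2"]
        pooled = infer_spots(ev, db, mode="parsimony", scope="pooled",
                             filter_config=PsmFilterConfig(min_peptides=1))
        # pooling still accepts both proteins but can no longer resolve
        # which homolog the shared peptides of each spot came from
        assert set(pooled["results"]["s1"].accepted) >= {"H1"}
        assert per["histogram"] == (2, 0, 0)

    def test_two_spots_same_protein(self):
        db = self._db_two_homologs()
        ev = {
            "a": [obs("DSTWHEVNR", spot="a"), obs("QPQQPFPQQ", spot="a")],
            "b": [obs("DSTWHEVNR", spot="b"), obs("QPQQPFPQQ", spot="b")],
        }
        out = infer_spots(ev, db, filter_config=PsmFilterConfig(min_peptides=1))
        assert [r.accepted for r in out["results"].values()] == [["H1"], ["H1"]]
        assert out["histogram"] == (2, 0, 0)


class TestFdr:
    def _db(self, n_targets, n_decoys):
        recs = [ProteinRecord(id=f"t{i}", sequence="ACDEF") for i in range(n_targets)]
        recs += [
            ProteinRecord(id=f"DECOY_t{i}", sequence="FEDCA", is_decoy=True)
            for i in range(n_decoys)
        ]
        return SequenceDatabase(recs)

    def test_formula(self):
        db = self._db(100, 2)
        assert estimate_fdr([f"t{i}" for i in range(100)], db).fdr == 0.0
        est = estimate_fdr([f"t{i}" for i in range(99)] + ["DECOY_t0"], db)
        assert est.fdr == pytest.approx(1 / 99)

    def test_scale_invariance(self):
        db = self._db(40, 4)
        one = estimate_fdr([f"t{i}" for i in range(20)] + ["DECOY_t0"], db)
        two = estimate_fdr([f"t{i}" for i in range(40)]
                           + ["DECOY_t0", "DECOY_t1"], db)
        assert one.fdr == pytest.approx(two.fdr)

    def test_zero_targets_with_decoy_is_infinite(self):
        db = self._db(1, 1)
        with pytest.warns(UserWarning):
            est = estimate_fdr(["DECOY_t0"], db)
        assert math.isinf(est.fdr)
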
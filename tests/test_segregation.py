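"""Effect filtering and inheritance-model segregation checks."""

import itertools

import pytest

from exomesieve.core import GenotypeCall, NormalizedVariant
from exomesieve.founders import Individual, Pedigree, cohort_founder_frequencies
from exomesieve.segregation import (
    CandidateCall,
    EffectAnnotation,
    FamilyConfiguration,
    InvalidModelError,
    candidate_variant_count,
    effect_filter,
    family_ablation,
    model_check,
    run_filtration,
    standard_ladder,
)

AUTO_V = NormalizedVariant("chr1", 100, "A", "T")
X_V = NormalizedVariant("chrX", 100, "A", "T")


def quintet(affected_sib=False):
    """proband (male, affected) + parents + 2 siblings."""
    return Pedigree(
        "F",
        [
            Individual("fa", "male", "unaffected"),
            Individual("mo", "female", "unaffected"),
            Individual("p", "male", "affected", "fa", "mo"),
            Individual(
                "s1", "female", "affected" if affected_sib else "unaffected",
                "fa", "mo",
            ),
            Individual("s2", "male", "unaffected", "fa", "mo"),
        ],
        proband_id="p",
    )


def config_of(ped, members):
    return FamilyConfiguration.from_members(ped, members)


def calls(ped, counts, ploidy=None):
    ploidy = ploidy or {}
    return {
        m: GenotypeCall(m, c, ploidy.get(m, 2)) if c >= 0
        else GenotypeCall(m, 0, ploidy.get(m, 2), missing=True)
        for m, c in counts.items()
    }


class TestEffectFilter:
    def test_frameshift_kept_intronic_boundary(self):
        anns = [
            EffectAnnotation(("chr1", 1, "A", "T"), "G1", "frameshift"),
            EffectAnnotation(("chr1", 2, "A", "T"), "G1", "intronic_near_splice", 20),
            EffectAnnotation(("chr1", 3, "A", "T"), "G1", "intronic_near_splice", 21),
            EffectAnnotation(("chr1", 4, "A", "T"), "G1", "other"),
        ]
        kept = effect_filter(anns)
        assert ("chr1", 1, "A", "T") in kept
        assert ("chr1", 2, "A", "T") in kept
        assert ("chr1", 3, "A", "T") not in kept
        assert ("chr1", 4, "A", "T") not in kept

    def test_random_tables_match_rowwise_rule(self, rng):
        classes = [
            "non_synonymous", "frameshift", "canonical_splice",
            "intronic_near_splice", "other",
        ]
        anns = []
        for i in range(200):
            cls = str(rng.choice(classes))
            dist = int(rng.integers(1, 40)) if cls == "intronic_near_splice" else None
            anns.append(EffectAnnotation(("chr1", i + 1, "A", "T"), "G", cls, dist))
        kept = effect_filter(anns)
        for a in anns:
            expected = a.effect_class not in ("other",) and not (
                a.effect_class == "intronic_near_splice" and a.splice_distance > 20
            )
            assert (a.key in kept) == expected


def oracle_model_check(variant, model, ped, included, call_map):
    """Independent flat re-statement of the model semantics (single variant).

    Written as literal per-member rules so it shares no code with the
    implementation's predicate machinery.
    """
    def cnt(mid):
        c = call_map.get(mid)
        if c is None or c.missing:
            return None
        return c.alt_count, c.ploidy

    members = {m.id: m for m in ped.members}
    pro = ped.proband_id
    father = next((m.id for m in ped.members if m.sex == "male" and m.is_founder), None)
    mother = next((m.id for m in ped.members if m.sex == "female" and m.is_founder), None)
    sibs = [m.id for m in ped.members if m.id not in (pro, father, mother)]

    def need(mid, test):
        if mid is None or mid not in included:
            return True
        g = cnt(mid)
        if g is None:
            return False  # conservative missing policy
        return test(*g)

    if model == "hom_recessive":
        rules = [need(pro, lambda c, p: c == 2),
                 need(father, lambda c, p: c == 1),
                 need(mother, lambda c, p: c == 1)]
        for s in sibs:
            if members[s].affected == "affected":
                rules.append(need(s, lambda c, p: c == 2))
            else:
                rules.append(need(s, lambda c, p: c < 2))
        return all(rules)
    if model == "de_novo_dominant":
        rules = [need(pro, lambda c, p: c == 1),
                 need(father, lambda c, p: c == 0),
                 need(mother, lambda c, p: c == 0)]
        for s in sibs:
            if members[s].affected == "affected":
                rules.append(need(s, lambda c, p: c >= 1))
            else:
                rules.append(need(s, lambda c, p: c == 0))
        return all(rules)
    if model == "x_linked":
        if members[pro].sex != "male":
            raise NotImplementedError
        rules = [need(pro, lambda c, p: c == p and c >= 1),
                 need(mother, lambda c, p: c == 1),
                 need(father, lambda c, p: c == 0)]
        for s in sibs:
            st, sx = members[s].affected, members[s].sex
            if st == "unaffected" and sx == "male":
                rules.append(need(s, lambda c, p: c == 0))
            elif st == "unaffected":
                rules.append(need(s, lambda c, p: c < 2))
            elif st == "affected" and sx == "male":
                rules.append(need(s, lambda c, p: c == p))
            else:
                rules.append(need(s, lambda c, p: c == 2))
        return all(rules)
    raise NotImplementedError(model)


class TestModelCheck:
    def test_trio_de_novo_definitional(self):
        ped = quintet()
        cfg = config_of(ped, ["p", "fa", "mo"])
        cv = calls(ped, {"p": 1, "fa": 0, "mo": 0})
        assert model_check(AUTO_V, "de_novo_dominant", ped, cfg, cv)
        cv = calls(ped, {"p": 1, "fa": 1, "mo": 0})
        assert not model_check(AUTO_V, "de_novo_dominant", ped, cfg, cv)

    def test_unaffected_hom_sibling_blocks_recessive(self):
        ped = quintet()
        cfg = config_of(ped, ["p", "fa", "mo", "s1"])
        cv = calls(ped, {"p": 2, "fa": 1, "mo": 1, "s1": 2})
        assert not model_check(AUTO_V, "hom_recessive", ped, cfg, cv)
        cv = calls(ped, {"p": 2, "fa": 1, "mo": 1, "s1": 1})
        assert model_check(AUTO_V, "hom_recessive", ped, cfg, cv)

    def test_x_linked_on_autosome_rejected(self):
        ped = quintet()
        cfg = config_of(ped, ["p"])
        with pytest.raises(InvalidModelError):
            model_check(AUTO_V, "x_linked", ped, cfg, calls(ped, {"p": 1}))

    def test_missing_policy(self):
        ped = quintet()
        cfg = config_of(ped, ["p", "fa", "mo"])
        cv = calls(ped, {"p": 1, "fa": -1, "mo": 0})
        assert not model_check(AUTO_V, "de_novo_dominant", ped, cfg, cv)
        assert model_check(
            AUTO_V, "de_novo_dominant", ped, cfg, cv, missing_policy="permissive"
        )

    @pytest.mark.parametrize("affected_sib", [False, True])
    @pytest.mark.parametrize(
        "model", ["hom_recessive", "de_novo_dominant", "x_linked"]
    )
    @pytest.mark.parametrize(
        "included",
        [("p",), ("p", "fa", "mo"), ("p", "fa", "mo", "s1"),
         ("p", "fa", "mo", "s1", "s2")],
    )
    def test_exhaustive_vectors_match_oracle(self, model, included, affected_sib):
        """Agreement with exhaustive enumeration of genotype vectors on a
        5-member family, for every configuration of included members."""
        ped = quintet(affected_sib)
        cfg = config_of(ped, list(included))
        variant = X_V if model == "x_linked" else AUTO_V
        # on X: males are hemizygous (ploidy 1)
        ploidy = (
            {"fa": 1, "p": 1, "s2": 1} if model == "x_linked" else {}
        )
        members = [m.id for m in ped.members]
        ranges = [range(0, ploidy.get(m, 2) + 1) for m in members]
        n_true = 0
        for vec in itertools.product(*ranges):
            cv = calls(ped, dict(zip(members, vec)), ploidy)
            got = model_check(variant, model, ped, cfg, cv)
            want = oracle_model_check(variant, model, ped, set(included), cv)
            assert got == want, (vec, model, included)
            n_true += got
        assert n_true > 0  # the model is satisfiable in every configuration


class TestCompoundHet:
    def setup_method(self):
        self.ped = quintet()
        self.v1 = NormalizedVariant("chr1", 100, "A", "T")
        self.v2 = NormalizedVariant("chr1", 200, "G", "C")

    def check(self, members, c1, c2):
        cfg = config_of(self.ped, members)
        return model_check(
            (self.v1, self.v2), "compound_het", self.ped, cfg,
            (calls(self.ped, c1), calls(self.ped, c2)),
        )

    def test_opposite_parents_accepted(self):
        assert self.check(
            ["p", "fa", "mo"],
            {"p": 1, "fa": 1, "mo": 0},
            {"p": 1, "fa": 0, "mo": 1},
        )

    def test_same_parent_pair_rejected_with_parents(self):
        assert not self.check(
            ["p", "fa", "mo"],
            {"p": 1, "fa": 1, "mo": 0},
            {"p": 1, "fa": 1, "mo": 0},
        )

    def test_singleton_mode_needs_no_phase(self):
        assert self.check(["p"], {"p": 1}, {"p": 1})

    def test_unaffected_carrier_of_both_blocks(self):
        assert not self.check(
            ["p", "fa", "mo", "s1"],
            {"p": 1, "fa": 1, "mo": 0, "s1": 1},
            {"p": 1, "fa": 0, "mo": 1, "s1": 1},
        )

    def test_proband_must_be_het_for_both(self):
        assert not self.check(["p"], {"p": 2}, {"p": 1})


class TestRunFiltrationOnSyntheticCohort:
    def test_planted_variants_recovered_with_their_model(self, ds_small, cohort_small):
        peds = {p.family_id: p for p in ds_small.pedigrees}
        for fam, specs in ds_small.truth.items():
            ped = peds[fam]
            freqs = cohort_founder_frequencies(cohort_small, ds_small.pedigrees, fam)
            cfg = FamilyConfiguration.from_members(ped, [m.id for m in ped.members])
            cands = run_filtration(cohort_small, ped, cfg, freqs, ds_small.annotations)
            for spec in specs:
                want_keys = {tuple(k[:1]) + (int(k[1]),) + tuple(k[2:]) for k in spec["keys"]}
                hits = [
                    c for c in cands
                    if c.model == spec["model"]
                    and want_keys <= {v.key for v in c.variants}
                ]
                assert hits, (fam, spec["model"])

    def test_common_variants_never_pass(self, ds_small, cohort_small):
        ped = ds_small.pedigrees[0]
        freqs = cohort_founder_frequencies(cohort_small, ds_small.pedigrees, ped.family_id)
        cfg = FamilyConfiguration.from_members(ped, [m.id for m in ped.members])
        cands = run_filtration(cohort_small, ped, cfg, freqs, ds_small.annotations)
        for c in cands:
            for v in c.variants:
                assert freqs[v.key].rarity in ("absent", "rare")

    def test_singleton_superset_of_trio(self, ds_small, cohort_small):
        for ped in ds_small.pedigrees[:3]:
            freqs = cohort_founder_frequencies(
                cohort_small, ds_small.pedigrees, ped.family_id
            )
            single = FamilyConfiguration.from_members(ped, [ped.proband_id])
            trio = FamilyConfiguration.from_members(
                ped,
                [ped.proband_id] + [p.id for p in ped.parents_of(ped.proband_id)],
            )
            vs = lambda cands: {v.key for c in cands for v in c.variants}
            v_single = vs(run_filtration(cohort_small, ped, single, freqs, ds_small.annotations))
            v_trio = vs(run_filtration(cohort_small, ped, trio, freqs, ds_small.annotations))
            assert v_trio <= v_single


class TestFamilyAblation:
    def test_counts_non_increasing_and_idempotent(self, ds_small, cohort_small):
        ped = ds_small.pedigrees[1]
        freqs = cohort_founder_frequencies(cohort_small, ds_small.pedigrees, ped.family_id)
        ladder = standard_ladder(ped)
        counts = [c for _, c in family_ablation(
            cohort_small, ped, ladder, freqs, ds_small.annotations
        )]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        # ladder of identical configurations gives identical counts
        same = [ladder[1], ladder[1], ladder[1]]
        res = family_ablation(cohort_small, ped, same, freqs, ds_small.annotations)
        assert len({c for _, c in res}) == 1

    def test_non_nested_ladder_rejected(self, ds_small, cohort_small):
        ped = ds_small.pedigrees[0]
        freqs = {}
        trio = standard_ladder(ped)[1]
        single = standard_ladder(ped)[0]
        with pytest.raises(ValueError, match="nested"):
            family_ablation(
                cohort_small, ped, [trio, single], freqs, ds_small.annotations
            )


class TestFamilyConfiguration:
    def test_labels(self):
        ped = quintet()
        assert config_of(ped, ["p"]).label == "singleton"
        assert config_of(ped, ["p", "fa", "mo"]).label == "trio"
        assert config_of(ped, ["p", "fa", "mo", "s1", "s2"]).label == "quintet"

    def test_proband_required(self):
        with pytest.raises(ValueError, match="proband"):
            config_of(quintet(), ["fa", "mo"])

    def test_single_parent_rejected(self):
        with pytest.raises(ValueError, match="together"):
            config_of(quintet(), ["p", "fa"])

    def test_candidate_call_validation(self):
        with pytest.raises(ValueError):
            CandidateCall((AUTO_V,), "compound_het", "F", "trio")
        with pytest.raises(ValueError):
            CandidateCall((AUTO_V, AUTO_V), "compound_het", "F", "trio")
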
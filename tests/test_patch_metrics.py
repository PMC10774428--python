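"""Patch kernel vs naive double-loop oracles; decomposition; SFvCSP algebra."""

import itertools
import math

import numpy as np
import pytest

from tapkit.config import RunConfig
from tapkit.core_model import Atom, FvStructure, Residue
from tapkit.patch_metrics import (KYTE_DOOLITTLE, ChargeAssignment,
                                  HydrophobicityScale, PairComponent,
                                  compute_profile, patch_score, pnc,
                                  position_contribution_table, ppc, psh,
                                  sfvcsp, top_components)
from tapkit.regions import (CdrVicinity, assign_regions, build_anchor_set,
                            build_cdr_vicinity, total_cdr_length)
from tapkit.surface import run_sasa_pipeline


def _res(chain, num, aa, coords, seq_index=None, icode=""):
    coords = np.atleast_2d(np.asarray(coords, float))
    atoms = [Atom(f"C{i or 'A'}", "C", c, 1.7) for i, c in enumerate(coords)]
    return Residue(chain, num, icode, aa, seq_index if seq_index is not None else num,
                   atoms=atoms)


def _vicinity(members):
    return CdrVicinity(anchors=list(members), members=list(members),
                       distance_cutoff=4.5)


def _all_exposed(members):
    return {r.key: True for r in members}


def naive_patch_oracle(members, exposure, weight_of, cutoff, exponent):
    """Independent O(n^2 m^2) evaluation: explicit double loop over residues
    and over their atom pairs for the minimum distance."""
    total = 0.0
    elig = [r for r in members if exposure[r.key] and weight_of(r) > 0]
    for a, b in itertools.combinations(elig, 2):
        best = math.inf
        for at_a in a.atoms:
            for at_b in b.atoms:
                best = min(best, math.dist(at_a.coord, at_b.coord))
        if best <= cutoff:
            total += weight_of(a) * weight_of(b) / best ** exponent
    return total


def test_hand_computed_three_residue_score():
    # pairwise distances 4, 5, 6 Å and weights 2.0, 1.5, 1.0
    members = [_res("H", 1, "A", [[0, 0, 0]]),
               _res("H", 2, "A", [[4, 0, 0]]),
               _res("H", 3, "A", [[0.625, 4.96078, 0]])]
    w = {("H", 1, ""): 2.0, ("H", 2, ""): 1.5, ("H", 3, ""): 1.0}
    score, comps = patch_score(_vicinity(members), _all_exposed(members),
                               lambda r: w[r.key], pair_cutoff=7.5, exponent=2)
    expected = 2.0 * 1.5 / 16 + 2.0 * 1.0 / 25 + 1.5 * 1.0 / 36
    assert score == pytest.approx(expected, rel=1e-4)
    assert len(comps) == 3


def test_no_pairs_and_cutoff_edge_cases():
    one = [_res("H", 1, "L", [[0, 0, 0]])]
    assert patch_score(_vicinity(one), _all_exposed(one), lambda r: 1.0) == (0.0, [])
    far = [_res("H", 1, "L", [[0, 0, 0]]), _res("H", 2, "L", [[8.0, 0, 0]])]
    score, comps = patch_score(_vicinity(far), _all_exposed(far), lambda r: 1.0,
                               pair_cutoff=7.5)
    assert score == 0.0 and comps == []
    empty = CdrVicinity(anchors=[], members=[], distance_cutoff=4.5)
    assert patch_score(empty, {}, lambda r: 1.0) == (0.0, [])


@pytest.mark.parametrize("seed", range(100))
def test_randomized_fixtures_match_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 10)
    aas = rng.choice(list(KYTE_DOOLITTLE), size=n)
    members = []
    for i, aa in enumerate(aas):
        coords = rng.uniform(0, 12, size=(rng.integers(1, 4), 3))
        members.append(_res("H" if i % 2 else "L", i + 1, aa, coords, seq_index=i))
    exposure = {r.key: bool(rng.random() > 0.2) for r in members}
    scale = HydrophobicityScale.kyte_doolittle()

    def weight(r):
        return scale.normalized[r.aa]

    score, comps = patch_score(_vicinity(members), exposure, weight,
                               pair_cutoff=7.5, exponent=2)
    oracle = naive_patch_oracle(members, exposure, weight, 7.5, 2)
    assert score == pytest.approx(oracle, rel=1e-9, abs=1e-12)
    assert score == pytest.approx(sum(c.contribution for c in comps),
                                  rel=1e-9, abs=1e-12)
    assert all(c.contribution >= 0 for c in comps)


def test_psh_order_preserving_and_charge_weights():
    geometry = [[0, 0, 0], [4, 0, 0], [0, 4, 0]]
    gly = [_res("H", i + 1, "G", [c]) for i, c in enumerate(geometry)]
    leu = [_res("H", i + 1, "L", [c]) for i, c in enumerate(geometry)]
    s_gly, _ = psh(_vicinity(gly), _all_exposed(gly))
    s_leu, _ = psh(_vicinity(leu), _all_exposed(leu))
    assert s_leu > s_gly > 0

    lysines = [_res("H", 1, "K", [[0, 0, 0]]), _res("H", 2, "K", [[4.0, 0, 0]])]
    s_ppc, comps = ppc(_vicinity(lysines), _all_exposed(lysines))
    assert s_ppc == pytest.approx(1.0 / 16)        # 1*1/4^2 = 0.0625
    assert comps[0].distance == pytest.approx(4.0)
    assert pnc(_vicinity(lysines), _all_exposed(lysines)) == (0.0, [])

    no_charge = [_res("H", 1, "S", [[0, 0, 0]]), _res("H", 2, "T", [[4.0, 0, 0]])]
    assert ppc(_vicinity(no_charge), _all_exposed(no_charge)) == (0.0, [])


def test_scale_equivariance():
    rng = np.random.default_rng(4)
    members = [_res("H", i + 1, "A", rng.uniform(0, 8, size=(2, 3)), seq_index=i)
               for i in range(6)]
    exp = _all_exposed(members)
    s1, _ = patch_score(_vicinity(members), exp, lambda r: 1.3)
    s2, _ = patch_score(_vicinity(members), exp, lambda r: 2.6)
    assert s2 == pytest.approx(4.0 * s1, rel=1e-12)


def _charged_fv(heavy_aas, light_aas):
    heavy = [_res("H", i + 1, aa, [[i * 10.0, 0, 0]], seq_index=i)
             for i, aa in enumerate(heavy_aas)]
    light = [_res("L", i + 1, aa, [[i * 10.0, 0, 40.0]], seq_index=i)
             for i, aa in enumerate(light_aas)]
    return FvStructure(id="q", heavy=heavy, light=light)


def test_sfvcsp_hand_example_and_symmetries():
    fv = _charged_fv("KKD", "DD")          # VH net +1, VL net -2
    exposure = {r.key: True for r in fv.residues()}
    charges = ChargeAssignment.default()
    assert sfvcsp(fv, exposure, charges) == pytest.approx(-2.0)

    # heavy net zero -> product zero regardless of light chain
    fv0 = _charged_fv("KD", "DDE")
    exp0 = {r.key: True for r in fv0.residues()}
    assert sfvcsp(fv0, exp0, charges) == 0.0

    # swapping chain labels preserves the score
    swapped = FvStructure(
        id="q", light=[_res("L", r.imgt_number, r.aa,
                            [a.coord for a in r.atoms], r.seq_index)
                       for r in fv.heavy],
        heavy=[_res("H", r.imgt_number, r.aa,
                    [a.coord for a in r.atoms], r.seq_index)
               for r in fv.light])
    exp_sw = {r.key: True for r in swapped.residues()}
    assert sfvcsp(swapped, exp_sw, charges) == pytest.approx(-2.0)

    # negating every charge: (-a)(-b) = ab; negating one chain: -(ab)
    neg = ChargeAssignment(per_aa={aa: -q for aa, q in charges.per_aa.items()})
    assert sfvcsp(fv, exposure, neg) == pytest.approx(sfvcsp(fv, exposure, charges))
    # buried residues drop out of the sums
    exposure[("H", 1, "")] = False          # lose one K -> VH net 0
    assert sfvcsp(fv, exposure, charges) == 0.0


def test_his_charge_is_configurable():
    fv = _charged_fv("HH", "DD")
    exposure = {r.key: True for r in fv.residues()}
    assert sfvcsp(fv, exposure, ChargeAssignment.default(0.1)) == pytest.approx(-0.4)
    assert sfvcsp(fv, exposure, ChargeAssignment.default(0.0)) == 0.0


def test_profile_determinism_and_internal_consistency(mini_fv, config, max_table):
    p1 = compute_profile(mini_fv, config, max_table)
    p2 = compute_profile(mini_fv, config, max_table)
    assert (p1.psh, p1.ppc, p1.pnc, p1.sfvcsp, p1.l_tot) == \
           (p2.psh, p2.ppc, p2.pnc, p2.sfvcsp, p2.l_tot)

    regions = assign_regions(mini_fv)
    assert p1.l_tot == total_cdr_length(mini_fv, regions)
    for attr, score in (("psh_components", p1.psh),
                        ("ppc_components", p1.ppc),
                        ("pnc_components", p1.pnc)):
        comps = getattr(p1, attr)
        assert score == pytest.approx(sum(c.contribution for c in comps),
                                      rel=1e-9, abs=1e-12)


def test_profile_composes_individually_tested_stages(mini_fv, config, max_table):
    profile = compute_profile(mini_fv, config, max_table)
    _, exposure = run_sasa_pipeline(mini_fv, config, max_table)
    regions = assign_regions(mini_fv)
    anchors = build_anchor_set(mini_fv, regions)
    vic = build_cdr_vicinity(mini_fv, anchors, exposure, config.vicinity_cutoff)
    assert profile.psh == pytest.approx(psh(vic, exposure, config=config)[0])
    assert profile.ppc == pytest.approx(ppc(vic, exposure, config=config)[0])
    assert profile.pnc == pytest.approx(pnc(vic, exposure, config=config)[0])
    assert profile.sfvcsp == pytest.approx(
        sfvcsp(mini_fv, exposure, scope=config.sfvcsp_scope))


def test_locality_distant_residue_changes_nothing(mini_fv, config, max_table):
    """A residue farther than pair_cutoff + vicinity_cutoff from every anchor
    cannot alter any patch score."""
    base = compute_profile(mini_fv, config, max_table)
    far = Residue("L", 200, "", "W", len(mini_fv.light),
                  atoms=[Atom("CA", "C", [500.0, 500.0, 500.0], 1.7),
                         Atom("CB", "C", [501.5, 500.0, 500.0], 1.7)])
    extended = FvStructure(id=mini_fv.id, heavy=mini_fv.heavy,
                           light=mini_fv.light + [far],
                           light_locus=mini_fv.light_locus)
    augmented = compute_profile(extended, config, max_table)
    assert augmented.psh == pytest.approx(base.psh, rel=1e-12)
    assert augmented.ppc == pytest.approx(base.ppc, rel=1e-12)
    assert augmented.pnc == pytest.approx(base.pnc, rel=1e-12)


def _random_components(rng, n):
    comps = []
    for i in range(n):
        ci, cj = rng.choice(["H", "L"], size=2)
        si, sj = int(rng.integers(0, 30)), int(rng.integers(0, 30))
        if ci == cj and si == sj:
            sj += 1
        comps.append(PairComponent(
            res_i=(ci, si + 1, ""), res_j=(cj, sj + 1, ""),
            aa_i="A", aa_j="V", seq_i=si, seq_j=sj,
            distance=float(rng.uniform(2, 7.5)),
            contribution=float(rng.choice([0.1, 0.25, 0.7, rng.uniform(0, 1)])),
            adjacent=(ci == cj and abs(si - sj) == 1)))
    return comps


def test_top_components_against_sort_oracle():
    rng = np.random.default_rng(9)
    for _ in range(20):
        comps = _random_components(rng, int(rng.integers(1, 40)))
        for adjacency, keep in (("adjacent", lambda c: c.adjacent),
                                ("non_adjacent", lambda c: not c.adjacent),
                                (None, lambda c: True)):
            got = top_components(comps, k=10, adjacency=adjacency)
            pool = [c for c in comps if keep(c)]
            expected = sorted(pool, key=lambda c: -c.contribution)[:10]
            assert [c.contribution for c in got] == \
                   [c.contribution for c in expected]
            assert all(keep(c) for c in got)
    assert len(top_components(_random_components(rng, 5), k=20)) == 5


def test_top_components_ties_broken_lexicographically():
    a = PairComponent(("H", 10, ""), ("H", 11, ""), "A", "A", 9, 10, 4.0, 0.5, True)
    b = PairComponent(("H", 2, ""), ("L", 5, ""), "A", "A", 1, 4, 4.0, 0.5, False)
    assert top_components([a, b], k=2)[0] is b


def test_position_contribution_table_hand_tally():
    def comp(ci, ni, cj, nj, contrib, adjacent=False):
        return PairComponent((ci, ni, ""), (cj, nj, ""), "A", "A",
                             ni, nj, 4.0, contrib, adjacent)

    from tapkit.patch_metrics import TapProfile
    p1 = TapProfile(id="a1", l_tot=40, psh=1, ppc=0, pnc=0, sfvcsp=0,
                    psh_components=[comp("H", 105, "H", 106, 0.9, adjacent=True),
                                    comp("H", 105, "L", 30, 0.5)])
    p2 = TapProfile(id="a2", l_tot=40, psh=1, ppc=0, pnc=0, sfvcsp=0,
                    psh_components=[comp("H", 105, "H", 50, 0.8)])
    p3 = TapProfile(id="a3", l_tot=40, psh=0, ppc=0, pnc=0, sfvcsp=0)
    counts = position_contribution_table([p1, p2, p3], k=20)
    assert counts == {("H", 105): 3, ("H", 106): 1, ("L", 30): 1, ("H", 50): 1}
    assert sum(counts.values()) <= 2 * 2 * 20 * 3
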
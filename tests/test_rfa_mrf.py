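"""MRF potentials and MAP inference against independent oracles.

The potential oracle (`brute_force_log_potential` in conftest) enumerates
every hidden molecule sequence explicitly (4^L) — no column factorisation,
no incremental state — so agreement validates the variable-elimination
implementation; the MAP tests exhaustively enumerate joint assignments to
validate the local-search optimiser.
"""

import itertools
import math

import numpy as np
import pytest

from rfaligner.rfa_mrf import (
    UNASSIGNED,
    InferenceConfig,
    MRFState,
    build_mrf,
    compute_log_potential,
    map_inference,
    score_assignment,
)
from rfaligner.simulator import decode, encode

from .conftest import (
    aln,
    toy_prior,
    brute_force_log_potential,
    make_fragment,
    make_molecule,
    make_prior,
    random_seq,
)


def exhaustive_map(graph, prior):
    """Enumerate every joint assignment by DFS over the incremental state;
    returns (best score, best choice tuple)."""
    state = MRFState(graph, prior)
    n = len(graph.fragments)
    best = [-np.inf, None]

    def rec(i):
        if i == n:
            if state.total > best[0] + 1e-12:
                best[0] = state.total
                best[1] = tuple(int(c) for c in state.choice)
            return
        for k in [UNASSIGNED] + list(range(len(graph.options[i]))):
            state.set_choice(i, k)
            rec(i + 1)
        state.set_choice(i, UNASSIGNED)

    rec(0)
    return best[0], best[1]


class TestPotential:
    def test_empty_molecule_is_log_one_minus_p_exist(self, prior):
        mol = make_molecule("ACGT" * 500)
        assert compute_log_potential(mol, [], prior) == pytest.approx(
            math.log(1 - prior.p_exist)
        )

    def test_matches_exhaustive_x_enumeration_on_4bp_molecule(self):
        """Two reads on a 4-bp molecule, theta=0.25: the column-factorised
        elimination must agree with the explicit 4^4 sum to 1e-9."""
        prior = toy_prior(theta=0.25)
        mol = make_molecule("ACGT")
        r1 = make_fragment("a", "ACGT", qual=20)
        r2 = make_fragment("b", "ACTT", qual=25)  # one mismatch
        assigned = [(r1, aln(0, 0)), (r2, aln(0, 0))]
        got = compute_log_potential(mol, assigned, prior)
        want = brute_force_log_potential(mol, assigned, prior)
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_x_enumeration_random(self, seed):
        rng = np.random.default_rng(seed)
        prior = toy_prior(theta=float(rng.uniform(1e-3, 0.3)))
        L = int(rng.integers(4, 7))
        mol = make_molecule(random_seq(rng, L))
        assigned = []
        for i in range(int(rng.integers(1, 4))):
            rl = int(rng.integers(2, L + 1))
            off = int(rng.integers(0, L - rl + 1))
            seq = random_seq(rng, rl)
            strand = "+" if rng.random() < 0.5 else "-"
            frag = make_fragment(f"r{i}", seq, qual=int(rng.integers(10, 40)),
                                 end_marker=rng.random() < 0.3)
            assigned.append((frag, aln(0, off, strand=strand)))
        got = compute_log_potential(mol, assigned, prior)
        want = brute_force_log_potential(mol, assigned, prior)
        assert got == pytest.approx(want, abs=1e-9)

    def test_single_mismatch_log_ratio_closed_form(self):
        """One read, one position differing: the potential difference is the
        hand-derived single-column elimination ratio."""
        theta, e = 1e-3, 1e-3  # qual 30
        prior = toy_prior(theta=theta)
        seq = "ACGTACGTAC"
        mol = make_molecule(seq)
        match = make_fragment("m", seq, qual=30)
        mism = make_fragment("x", "ACGTTCGTAC", qual=30)  # pos 4 A->T
        lp_match = compute_log_potential(mol, [(match, aln(0, 0))], prior)
        lp_mism = compute_log_potential(mol, [(mism, aln(0, 0))], prior)
        num = (1 - theta) * e / 3 + (theta / 3) * (1 - e) + (2 * theta / 3) * (e / 3)
        den = (1 - theta) * (1 - e) + theta * e / 3
        assert lp_mism - lp_match == pytest.approx(math.log(num / den), abs=1e-9)

    def test_indel_penalty_applied_per_event(self):
        prior = toy_prior()
        mol = make_molecule(random_seq(np.random.default_rng(0), 60))
        frag = make_fragment("r", mol.contig.sequence[:20] + mol.contig.sequence[21:41])
        gapless = compute_log_potential(
            mol, [(make_fragment("r", mol.contig.sequence[:40]), aln(0, 0))], prior
        )
        with_del = compute_log_potential(
            mol, [(frag, aln(0, 0, cigar="20M1D20M"))], prior
        )
        assert with_del < gapless
        assert with_del - gapless == pytest.approx(math.log(1e-4), abs=1e-6)


def two_copy_graph(rng, prior, n_reads=8, L=60, divergence=0.02,
                   qual=30, err_rate=0.0):
    # NB: pair with toy_prior() so molecule sizes/densities are plausible
    """Two homologous contigs; reads drawn from copy 0 with candidates in
    both copies."""
    s0 = encode(random_seq(rng, L))
    s1 = s0.copy()
    n_div = max(1, int(divergence * L))
    pos = rng.choice(L, size=n_div, replace=False)
    s1[pos] = (s1[pos] + rng.integers(1, 4, size=n_div)) % 4
    m0 = make_molecule(decode(s0), cloud_id=0, origin_start=0)
    m1 = make_molecule(decode(s1), cloud_id=1, origin_start=100_000)
    rl = 20
    frags = []
    for i in range(n_reads):
        off = int(rng.integers(0, L - rl + 1))
        bases = s0[off : off + rl].copy()
        errs = rng.random(rl) < err_rate
        bases[errs] = (bases[errs] + rng.integers(1, 4, size=int(errs.sum())).astype(np.uint8)) % 4
        mm1 = int((bases != s1[off : off + rl]).sum())
        cands = [aln(0, off, score=-6.0 * int(errs.sum())),
                 aln(1, off, score=-6.0 * mm1)]
        cands.sort(key=lambda a: (-a.score, a.contig_id))
        frags.append(make_fragment(f"r{i}", decode(bases), qual=qual,
                                   alignments=cands))
    graph = build_mrf(frags, [m0, m1])
    return graph


class TestGraphAndScore:
    def test_incidence_matches_brute_force_scan(self, rng):
        prior = toy_prior()
        graph = two_copy_graph(rng, prior, n_reads=10)
        for n, frag in enumerate(graph.fragments):
            want = {m.index for m in graph.molecules
                    for a in frag.alignments if a.contig_id == m.cloud_id}
            assert graph.attached_molecules(n) == want

    def test_molecule_without_reads_dropped(self, prior):
        m0 = make_molecule("ACGT" * 20, cloud_id=0)
        m1 = make_molecule("TTTT" * 20, cloud_id=1, origin_start=5000)
        frags = [make_fragment("r", "ACGT" * 5, alignments=[aln(0, 0)])]
        graph = build_mrf(frags, [m0, m1])
        assert [m.cloud_id for m in graph.molecules] == [0]

    def test_all_unassigned_score(self, rng):
        prior = toy_prior(p_exist=0.4)
        graph = two_copy_graph(rng, prior, n_reads=5)
        a = MRFState(graph, prior).assignment()
        want = len(graph.molecules) * math.log(1 - prior.p_exist) + sum(
            math.log(prior.p_offtarget) + len(f.seq) * math.log(0.25)
            for f in graph.fragments
        )
        assert a.score == pytest.approx(want)
        assert score_assignment(graph, a, prior) == pytest.approx(want)

    def test_score_invariant_under_molecule_relabeling(self, rng):
        prior = toy_prior()
        graph = two_copy_graph(rng, prior, n_reads=6)
        assignment, _ = map_inference(graph, prior, InferenceConfig(seed=0))
        s1 = score_assignment(graph, assignment, prior)
        # relabel: swap the two molecules (and remap domain indices)
        for m in graph.molecules:
            m.index = 1 - m.index
        graph.molecules.reverse()
        graph.options = [
            [(a, 1 - mi) for a, mi in opts] for opts in graph.options
        ]
        s2 = score_assignment(graph, assignment, prior)
        assert s2 == pytest.approx(s1, abs=1e-6)

    def test_incremental_score_matches_recomputation(self, rng):
        prior = toy_prior()
        graph = two_copy_graph(rng, prior, n_reads=10, err_rate=0.02)
        state = MRFState(graph, prior)
        r = np.random.default_rng(3)
        for _ in range(200):
            n = int(r.integers(0, len(graph.fragments)))
            k = int(r.integers(-1, len(graph.options[n])))
            state.set_choice(n, k)
        assert state.total == pytest.approx(
            score_assignment(graph, state.assignment(), prior), abs=1e-6
        )


class TestMapInference:
    def test_single_candidate_reads_take_it(self, rng):
        prior = toy_prior()
        mol = make_molecule(random_seq(rng, 40))
        frags = [
            make_fragment(f"r{i}", mol.contig.sequence[4 * i : 4 * i + 12],
                          alignments=[aln(0, 4 * i)])
            for i in range(6)
        ]
        graph = build_mrf(frags, [mol])
        a, _ = map_inference(graph, prior, InferenceConfig(seed=0, restarts=1))
        assert all(k == 0 for k in a.choice)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        prior = toy_prior(p_exist=0.5)
        graph = two_copy_graph(rng, prior, n_reads=int(rng.integers(4, 7)),
                               divergence=0.05, err_rate=0.05)
        want_score, _ = exhaustive_map(graph, prior)
        a, _ = map_inference(graph, prior, InferenceConfig(seed=seed))
        assert a.score == pytest.approx(want_score, abs=1e-6)

    def test_repeat_disambiguation_converges_to_consistent_copy(self):
        """Variant-bearing reads shared between two 98%-identity copies:
        all reads converge to the copy consistent with every read."""
        rng = np.random.default_rng(42)
        prior = toy_prior(p_exist=0.5, frag_mu=math.log(100.0))
        graph = two_copy_graph(rng, prior, n_reads=10, L=100,
                               divergence=0.02, err_rate=0.0)
        want_score, want_choice = exhaustive_map(graph, prior)
        a, state = map_inference(graph, prior, InferenceConfig(seed=0))
        assert a.score == pytest.approx(want_score, abs=1e-6)
        # every read placed on the true (consistent) copy 0
        placed = {state.graph.options[n][k][1]
                  for n, k in enumerate(a.choice) if k != UNASSIGNED}
        true_mol = [m.index for m in graph.molecules if m.cloud_id == 0][0]
        assert placed == {true_mol}

    def test_local_maximum_no_single_move_improves(self, rng):
        prior = toy_prior()
        graph = two_copy_graph(rng, prior, n_reads=8, err_rate=0.03)
        a, state = map_inference(graph, prior, InferenceConfig(seed=1))
        base = state.total
        for n in range(len(graph.fragments)):
            cur = int(state.choice[n])
            for k in [UNASSIGNED] + list(range(len(graph.options[n]))):
                state.set_choice(n, k)
                assert state.total <= base + 1e-9
            state.set_choice(n, cur)

    def test_deterministic_for_fixed_seed(self, rng):
        prior = toy_prior()
        graph = two_copy_graph(rng, prior, n_reads=10, err_rate=0.02)
        a1, _ = map_inference(graph, prior, InferenceConfig(seed=5))
        a2, _ = map_inference(graph, prior, InferenceConfig(seed=5))
        assert np.array_equal(a1.choice, a2.choice)
        assert a1.score == a2.score

    def test_potential_cost_linear_in_aligned_bases(self, prior):
        """Operation-count instrumentation: columns touched per add_read
        equal the read length, independent of molecule size."""
        from rfaligner.rfa_mrf import MoleculeScorer

        rng = np.random.default_rng(0)
        touched = []
        for L in (200, 2000):
            mol = make_molecule(random_seq(rng, L))
            sc = MoleculeScorer(mol, prior)
            frag = make_fragment("r", random_seq(rng, 50))
            b, q, cols, _ = sc._columns(frag, aln(0, 10))
            touched.append(len(cols))
            sc.add_read(frag, aln(0, 10))
        assert touched[0] == touched[1] == 50
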
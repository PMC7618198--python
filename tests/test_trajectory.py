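"""Trajectory design: invariants, timing, and a brute-force feasibility oracle.

The oracle enumerates every assignment of readout lines to echoes that
satisfies complementarity, equal per-echo stride and per-echo
collinearity with parallel lines, and classifies its echo-time spacing
by the same conventions the constructor uses (exact line offsets for
interleaved assignments; block spacing for sequential ones).  It shares
no code with the constructor.
"""

import itertools

import numpy as np
import pytest

from repimap.trajectory import (
    InfeasibleTrajectoryError,
    Trajectory,
    design_meepi,
    design_repi,
    echo_times,
    per_echo_sampling,
    validate,
)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_assignments(n_pe, n_echoes, dte_factor, R=1):
    """Enumerate all valid rEPI line-to-echo assignments for small n_pe.

    Returns a list of canonical sequences [(p, echo), ...] indexed by
    time slot, in undersampled units p = ky / R.
    """
    P = n_pe // R
    L = P // n_echoes
    found = []
    # common time stride d; echo time-blocks are APs (start, stride d)
    for d in range(1, P + 1):
        span = (L - 1) * d
        starts_all = [s for s in range(P - span)]
        # choose an ordered tuple of starts, one per echo, whose APs tile [0, P)
        for starts in itertools.permutations(starts_all, n_echoes):
            slots = []
            ok = True
            used = set()
            for s in starts:
                ap = set(range(s, s + span + 1, d))
                if used & ap:
                    ok = False
                    break
                used |= ap
            if not ok or len(used) != P:
                continue
            # residue-class (ky offset) permutation per echo
            for u in itertools.permutations(range(n_echoes)):
                seq = [None] * P
                offsets = []
                feasible = True
                for e in range(n_echoes):
                    # echo e sweeps its class ascending along its AP
                    for j in range(L):
                        t = starts[e] + j * d
                        p = u[e] + j * n_echoes
                        seq[t] = (p, e)
                    # line: p = u_e + n_echoes*(t - start_e)/d ; time offset
                    # at fixed p relative to echo 0's line:
                    if d == n_echoes:  # interleaved: slope 1, exact offsets
                        offsets.append(starts[e] - u[e])
                    elif d == 1:  # sequential blocks: nominal offset = block start
                        offsets.append(starts[e])
                    else:
                        feasible = False
                if not feasible:
                    continue
                base = offsets[0]
                if d == 1:
                    # echo-time order must follow block order with spacing L
                    if any(offsets[e] - base != e * L for e in range(n_echoes)):
                        continue
                    if dte_factor != L or L < 2:
                        continue
                else:
                    if any(
                        offsets[e] - base != dte_factor * e for e in range(n_echoes)
                    ):
                        continue
                found.append(tuple(seq))
    return sorted(set(found))


def oracle_feasible(n_echoes, dte_factor, n_pe_max=12):
    """Search all matrix sizes up to n_pe_max for a valid assignment."""
    best = []
    for n_pe in range(2 * n_echoes, n_pe_max + 1):
        if n_pe % n_echoes:
            continue
        sols = brute_force_assignments(n_pe, n_echoes, dte_factor)
        if sols:
            best.append((n_pe, len(sols)))
    return best


# ---------------------------------------------------------------------------
# constructor behaviour
# ---------------------------------------------------------------------------


class TestDesignRepi:
    def test_fig_1c_three_echo_interleave(self):
        """12 lines, 3 echoes, dTE = 2 esp: 4 lines/echo, stride 3, zig-zag."""
        tr = design_repi(12, 3, 2, R=1, esp=0.76, te1=30.0)
        assert len(tr.lines) == 12
        assert validate(tr) == []
        _, masks = per_echo_sampling(tr)
        assert masks.sum(axis=1).tolist() == [4, 4, 4]
        for e in range(3):
            kys = np.flatnonzero(masks[e])
            assert np.all(np.diff(kys) == 3)
        # zig-zag: each consecutive triplet of lines is spatially adjacent
        kys_t = [ln.ky for ln in tr.lines]
        for i in range(0, 12, 3):
            trip = kys_t[i : i + 3]
            assert max(trip) - min(trip) == 2

    def test_mirrored_direction_is_the_ascending_sequence(self):
        tr = design_repi(12, 3, 2, pe_direction=-1)
        assert [ln.ky for ln in tr.lines][:3] == [2, 1, 0]

    def test_two_echo_unit_dte_infeasible(self):
        with pytest.raises(InfeasibleTrajectoryError, match="infeasible"):
            design_repi(8, 2, 1)

    def test_non_divisible_matrix_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            design_repi(64, 3, 2, R=2)

    def test_three_echo_triple_dte_has_multiple_assignments(self):
        tr = design_repi(9, 3, 3)
        assert validate(tr) == []
        assert tr.n_assignments > 1

    def test_readout_duration_matches_conventional_epi(self):
        """Same k-space coverage in the same time as single-shot EPI."""
        tr = design_repi(48, 3, 2, R=2, esp=0.8)
        epi = design_meepi(48, 1, R=2, esp=0.8)
        assert tr.readout_duration_ms == pytest.approx(epi.readout_duration_ms)
        me = design_meepi(48, 3, R=2, esp=0.8)
        assert me.readout_duration_ms == pytest.approx(3 * tr.readout_duration_ms)

    @pytest.mark.parametrize("n_pe,ne,k,R", [(12, 3, 2, 1), (48, 3, 2, 2), (9, 3, 3, 1), (24, 2, 2, 2), (66, 3, 2, 2)])
    def test_constructed_trajectories_validate(self, n_pe, ne, k, R):
        tr = design_repi(n_pe, ne, k, R=R)
        assert validate(tr) == []
        # disjoint union covering the stride-R lattice
        _, masks = per_echo_sampling(tr)
        assert masks.any(axis=0).sum() == n_pe // R
        assert (masks.sum(axis=0) <= 1).all()
        # ky lattice contains the k-space center line
        assert masks.any(axis=0)[n_pe // 2]


class TestDesignMeepi:
    def test_printed_r2_protocol_dte(self):
        """TE2-TE1 of the matrix-128 R=2 protocol: (128/2) x 0.76 ms."""
        tr = design_meepi(128, 2, R=2, esp=0.76, te1=31.0)
        tes, dte = echo_times(tr)
        assert dte == pytest.approx(48.64)
        assert tes == pytest.approx([31.0, 79.64])

    def test_single_echo_is_conventional_epi(self):
        tr = design_meepi(8, 1, R=1)
        assert len(tr.lines) == 8
        assert sorted(ln.ky for ln in tr.lines) == list(range(8))
        assert len({ln.echo for ln in tr.lines}) == 1

    def test_sequential_echo_blocks(self):
        tr = design_meepi(12, 3, R=1)
        assert len(tr.lines) == 36
        for ln in tr.lines:
            assert ln.echo == ln.t // 12

    def test_identical_masks_across_echoes(self):
        factor, masks = per_echo_sampling(design_meepi(16, 2, R=2))
        assert factor == 2
        assert np.array_equal(masks[0], masks[1])


class TestEchoTimes:
    def test_repi_dte_is_dte_factor_times_esp(self):
        _, dte = echo_times(design_repi(12, 3, 2, esp=0.76))
        assert dte == pytest.approx(1.52)
        _, dte2 = echo_times(design_repi(12, 3, 2, esp=1.0))
        assert dte2 == pytest.approx(2.0)

    def test_meepi_full_matrix_dte(self):
        _, dte = echo_times(design_meepi(128, 2, R=1, esp=0.76))
        assert dte == pytest.approx(97.28)

    def test_te_list_arithmetic(self):
        tes, dte = echo_times(design_repi(12, 3, 2, esp=0.76, te1=30.0))
        assert np.allclose(np.diff(tes), dte)
        assert tes[0] == 30.0


class TestPerEchoSampling:
    @pytest.mark.parametrize(
        "builder,kwargs,factor",
        [
            (design_repi, dict(n_pe=48, n_echoes=3, dte_factor=2, R=2), 6),
            (design_repi, dict(n_pe=12, n_echoes=3, dte_factor=2, R=1), 3),
            (design_meepi, dict(n_pe=16, n_echoes=2, R=2), 2),
        ],
    )
    def test_undersampling_factor(self, builder, kwargs, factor):
        f, _ = per_echo_sampling(builder(**kwargs))
        assert f == factor


class TestValidate:
    def test_flags_duplicated_ky(self):
        tr = design_repi(12, 3, 2)
        tr.lines[3] = type(tr.lines[3])(t=3, ky=tr.lines[0].ky, echo=0)
        report = validate(tr)
        assert any("complementarity" in r for r in report)

    def test_flags_unequal_stride(self):
        tr = design_meepi(8, 2, R=1)
        # me-EPI echoes resample the same lines: complementarity flagged
        assert any("complementarity" in r for r in validate(tr))

    def test_flags_noncollinear_echo(self):
        tr = design_repi(12, 3, 2)
        # swap the ky of two same-echo lines to break collinearity only
        idx = [i for i, ln in enumerate(tr.lines) if ln.echo == 0]
        L = type(tr.lines[0])
        a, b = idx[0], idx[1]
        tr.lines[a], tr.lines[b] = (
            L(t=tr.lines[a].t, ky=tr.lines[b].ky, echo=0),
            L(t=tr.lines[b].t, ky=tr.lines[a].ky, echo=0),
        )
        assert any("collinear" in r or "stride" in r for r in validate(tr))


class TestFeasibilityOracle:
    """Brute-force enumeration reproduces the feasibility table for
    2-3 echoes and dTE factors 1-3 at matrix sizes up to 12."""

    @pytest.mark.parametrize("ne,k", [(2, 1), (2, 2), (2, 3), (3, 1), (3, 2), (3, 3)])
    def test_oracle_agrees_with_constructor(self, ne, k):
        cells = oracle_feasible(ne, k, n_pe_max=12)
        constructor_ok = []
        for n_pe in range(2 * ne, 13):
            if n_pe % ne:
                continue
            try:
                design_repi(n_pe, ne, k)
                constructor_ok.append(n_pe)
            except InfeasibleTrajectoryError:
                pass
        assert [n for n, _ in cells] == constructor_ok

    def test_feasibility_pattern(self):
        """2-echo unit-dTE is infeasible everywhere; 3-echo triple-dTE
        admits multiple assignments; the remaining cells are feasible."""
        assert oracle_feasible(2, 1) == []
        assert oracle_feasible(2, 2) != []
        assert oracle_feasible(2, 3) != []
        assert oracle_feasible(3, 1) != []
        assert oracle_feasible(3, 2) != []
        multi = oracle_feasible(3, 3)
        assert multi and any(count > 1 for _, count in multi)

    def test_constructor_solution_is_among_oracle_solutions(self):
        tr = design_repi(12, 3, 2, pe_direction=-1)  # ascending units
        seq = tuple((ln.ky, ln.echo) for ln in tr.lines)
        assert seq in brute_force_assignments(12, 3, 2)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        tr = design_repi(48, 3, 2, R=2, esp=0.76, te1=31.0)
        p = tmp_path / "traj.json"
        tr.save(p)
        tr2 = Trajectory.load(p)
        assert tr2.to_dict() == tr.to_dict()
        assert validate(tr2) == []
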
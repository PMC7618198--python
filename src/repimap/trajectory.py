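"""EPI, multi-echo EPI and blip-rewound EPI (rEPI) sampling trajectories.

A single-shot EPI readout acquires one k-space line per echo-spacing
interval.  In the ``k_y``-t plane a conventional EPI readout is a single
straight line; multi-echo EPI (me-EPI) acquires several images
sequentially (several widely separated lines); blip-rewound EPI (rEPI)
interleaves the images by inserting periodic rewinder blips, so the lines
of the individual echo images are temporally adjacent.  Interleaving
decouples the echo-time difference dTE from the number of phase-encode
lines: dTE becomes a small integer multiple of the echo spacing, which is
what makes single-readout B0 mapping robust to phase wrapping.

Two design principles constrain a valid rEPI assignment of readout lines
to echo images:

1. *equal per-echo undersampling* -- every echo image samples ky with the
   same constant stride ``n_echoes * R``, so all echoes share the same
   geometric distortion;
2. *complementary lines* -- no ky line is acquired by more than one echo,
   so the joint reconstruction sees every acquired line once.

Together with the requirement that each echo's (t, ky) samples lie on a
straight line offset ``dte_factor * e`` echo spacings from echo 0's line,
these principles admit exactly two assignment families (for 2 and 3
echoes; see :func:`design_repi`):

* the **interleaved** family, time stride ``n_echoes`` between successive
  lines of one echo, feasible for ``dte_factor == 2`` at any echo count
  and for ``dte_factor == 1`` at odd echo counts only;
* the **sequential** family (me-EPI-like blocks with complementary ky
  sets -- the "rEPI with one large rewinder" limit), feasible exactly
  when ``dte_factor`` equals the number of lines per echo.

2-echo rEPI with dTE = 1 x echo spacing is therefore infeasible, and
3-echo rEPI with dTE = 3 x echo spacing (9 lines, R=1) admits several
inequivalent assignments; the constructor fixes one canonically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

__all__ = [
    "Trajectory",
    "TrajectoryLine",
    "InfeasibleTrajectoryError",
    "design_repi",
    "design_meepi",
    "echo_times",
    "per_echo_sampling",
    "validate",
]


class InfeasibleTrajectoryError(ValueError):
    """No line-to-echo assignment satisfies both rEPI design principles."""


@dataclass(frozen=True)
class TrajectoryLine:
    """One acquired readout line: time index, ky index and echo label."""

    t: int
    ky: int
    echo: int


@dataclass
class Trajectory:
    """Ordered single-shot sampling trajectory in ky-t space.

    ``lines`` holds one record per acquired readout line in acquisition
    order; the physical acquisition time of line ``i`` in milliseconds is
    ``te1_offset_ms + lines[i].t * esp_ms``, where ``te1_offset_ms`` is
    chosen so that echo 0 crosses the ky center at ``te1_ms``.
    """

    n_pe: int
    n_readout: int
    n_echoes: int
    R: int
    esp_ms: float
    dte_factor: int
    lines: list[TrajectoryLine]
    te1_ms: float
    pe_direction: int = 1
    style: str = "repi"
    n_assignments: int = 1
    te1_offset_ms: float = field(default=0.0)

    # -- timing ---------------------------------------------------------

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def readout_duration_ms(self) -> float:
        """Duration of the full readout train (one line per esp)."""
        return self.n_lines * self.esp_ms

    def line_times_ms(self) -> list[float]:
        """Physical acquisition time of every line, in acquisition order."""
        return [self.te1_offset_ms + ln.t * self.esp_ms for ln in self.lines]

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_pe": self.n_pe,
            "n_readout": self.n_readout,
            "n_echoes": self.n_echoes,
            "R": self.R,
            "esp_ms": self.esp_ms,
            "dte_factor": self.dte_factor,
            "te1_ms": self.te1_ms,
            "pe_direction": self.pe_direction,
            "style": self.style,
            "n_assignments": self.n_assignments,
            "te1_offset_ms": self.te1_offset_ms,
            "lines": [[ln.t, ln.ky, ln.echo] for ln in self.lines],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        lines = [TrajectoryLine(int(t), int(ky), int(e)) for t, ky, e in d["lines"]]
        return cls(
            n_pe=int(d["n_pe"]),
            n_readout=int(d["n_readout"]),
            n_echoes=int(d["n_echoes"]),
            R=int(d["R"]),
            esp_ms=float(d["esp_ms"]),
            dte_factor=int(d["dte_factor"]),
            lines=lines,
            te1_ms=float(d["te1_ms"]),
            pe_direction=int(d["pe_direction"]),
            style=d.get("style", "repi"),
            n_assignments=int(d.get("n_assignments", 1)),
            te1_offset_ms=float(d.get("te1_offset_ms", 0.0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Trajectory":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# assignment search (in undersampled "p" units: ky = p * R)
# ---------------------------------------------------------------------------


def _interleaved_assignments(n_echoes: int, k: int) -> list[tuple[tuple, tuple]]:
    """All (m, u) start-slot / ky-offset permutation pairs for the
    interleaved family.

    Echo ``e`` samples time slots ``m[e] + j*n_echoes`` and p indices
    ``u[e] + j*n_echoes`` (unit slope), so its line is time-offset
    ``m[e] - u[e]`` from a common reference; exact echo-time spacing
    requires ``m[e] - u[e] = c + k*e`` for some integer ``c``.
    """
    two_c = -k * (n_echoes - 1)
    if two_c % 2:
        return []  # offsets would need a half-integer anchor
    c = two_c // 2
    sols = []
    slots = range(n_echoes)
    for u in itertools.permutations(slots):
        m = tuple(u[e] + k * e + c for e in slots)
        if sorted(m) == list(slots):
            sols.append((m, u))
    return sols


def _sequential_assignments(n_echoes: int, lines_per_echo: int) -> list[tuple[tuple, tuple]]:
    """All (block-start, ky-offset) pairs for the sequential family.

    Echo ``e`` occupies the time block ``[e*L, (e+1)*L)`` and sweeps its
    ky residue class at slope ``n_echoes`` p per line; the nominal
    echo-time spacing is the block length ``L``.
    """
    L = lines_per_echo
    return [
        (tuple(e * L for e in range(n_echoes)), u)
        for u in itertools.permutations(range(n_echoes))
    ]


def _assignment_to_sequence(
    m: tuple, u: tuple, n_echoes: int, lines_per_echo: int, stride: int
) -> list[tuple[int, int]]:
    """Expand an assignment into [(p, echo), ...] indexed by time slot.

    ``stride`` is the time stride between successive lines of one echo
    (``n_echoes`` for interleaved, 1 for sequential).
    """
    n_lines = n_echoes * lines_per_echo
    seq: list[tuple[int, int] | None] = [None] * n_lines
    for e in range(n_echoes):
        for j in range(lines_per_echo):
            t = m[e] + j * stride
            p = u[e] + j * n_echoes
            if seq[t] is not None:
                raise AssertionError("overlapping assignment")
            seq[t] = (p, e)
    assert all(s is not None for s in seq)
    return seq  # type: ignore[return-value]


def _canonical_key(seq: list[tuple[int, int]]) -> tuple:
    return tuple(seq)


def _mirror_reverse(seq: list[tuple[int, int]], n_echoes: int) -> list[tuple[int, int]]:
    """Time-reversed, ky-mirrored, echo-relabelled copy of a sequence.

    Playing a readout backwards with the opposite phase-encode polarity
    yields the same physical acquisition; echo labels reverse because the
    echo-time order flips.
    """
    P = len(seq)
    return [(P - 1 - p, n_echoes - 1 - e) for (p, e) in reversed(seq)]


def _count_classes(seqs: list[list[tuple[int, int]]], n_echoes: int) -> int:
    seen: set[tuple] = set()
    classes = 0
    for s in seqs:
        key = _canonical_key(s)
        if key in seen:
            continue
        classes += 1
        seen.add(key)
        seen.add(_canonical_key(_mirror_reverse(s, n_echoes)))
    return classes


def _total_blip(seq: list[tuple[int, int]]) -> int:
    return sum(abs(b[0] - a[0]) for a, b in zip(seq, seq[1:]))


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------


def design_repi(
    n_pe: int,
    n_echoes: int,
    dte_factor: int,
    R: int = 1,
    esp: float = 0.76,
    te1: float = 30.0,
    n_readout: int | None = None,
    pe_direction: int = 1,
) -> Trajectory:
    """Design a blip-rewound EPI trajectory.

    Parameters
    ----------
    n_pe : full phase-encode matrix size (number of ky grid lines).
    n_echoes : number of EPI images acquired per readout (>= 2).
    dte_factor : dTE in units of the echo spacing (dTE = dte_factor * esp).
    R : parallel-imaging undersampling factor along ky.
    esp : echo spacing in ms.
    te1 : echo time of the first echo in ms.
    n_readout : readout matrix size (defaults to ``n_pe``).
    pe_direction : +1 (posterior-anterior) or -1; mirrors the ky order.

    Returns
    -------
    Trajectory
        ``n_pe // R`` lines covering ky with stride ``R``; echo ``e``
        samples a disjoint ky subset of stride ``n_echoes * R`` along a
        straight line in ky-t space offset ``dte_factor * e`` echo
        spacings from echo 0.

    Raises
    ------
    InfeasibleTrajectoryError
        If no assignment satisfies both design principles (for example
        2 echoes with ``dte_factor=1``, at any matrix size).
    ValueError
        If ``n_pe`` is not divisible by ``n_echoes * R``.

    Notes
    -----
    When several inequivalent assignments exist (for example 3 echoes
    with ``dte_factor=3`` at 9 lines), the constructor fixes one
    canonically: the assignment minimizing the total ky distance
    travelled (smallest rewinder blips, hence smallest eddy-current
    burden), ties broken by lexicographically smallest ky order.  The
    number of inequivalent assignments is recorded in
    ``Trajectory.n_assignments``.
    """
    if n_echoes < 2:
        raise ValueError("rEPI needs at least 2 echoes")
    if dte_factor < 1:
        raise ValueError("dte_factor must be >= 1")
    if R < 1:
        raise ValueError("R must be >= 1")
    if pe_direction not in (1, -1):
        raise ValueError("pe_direction must be +1 or -1")
    if n_pe % (n_echoes * R):
        raise ValueError(
            f"n_pe={n_pe} not divisible by n_echoes*R={n_echoes * R}"
        )
    P = n_pe // R
    L = P // n_echoes  # lines per echo

    candidates: list[tuple[list[tuple[int, int]], int]] = []
    for m, u in _interleaved_assignments(n_echoes, dte_factor):
        candidates.append(
            (_assignment_to_sequence(m, u, n_echoes, L, n_echoes), n_echoes)
        )
    if dte_factor == L and L >= 2:
        for m, u in _sequential_assignments(n_echoes, L):
            candidates.append((_assignment_to_sequence(m, u, n_echoes, L, 1), 1))
    if not candidates:
        raise InfeasibleTrajectoryError(
            f"infeasible configuration: no rEPI assignment with "
            f"{n_echoes} echoes and dTE = {dte_factor} x echo spacing "
            f"at {P} lines satisfies both design principles"
        )

    n_classes = _count_classes([seq for seq, _ in candidates], n_echoes)
    best_seq = min(
        (seq for seq, _ in candidates),
        key=lambda s: (_total_blip(s), [p for p, _ in s]),
    )
    return _build(
        best_seq, n_pe, n_echoes, R, esp, dte_factor, te1,
        n_readout, pe_direction, "repi", n_classes,
    )


def design_meepi(
    n_pe: int,
    n_echoes: int,
    R: int = 1,
    esp: float = 0.76,
    te1: float = 30.0,
    n_readout: int | None = None,
    pe_direction: int = 1,
) -> Trajectory:
    """Design a sequential multi-echo EPI trajectory.

    Each echo image sweeps the *same* ky set (stride ``R``) in turn, so
    dTE equals the per-image readout length ``(n_pe / R) * esp``.  With
    ``n_echoes=1`` this is conventional single-shot EPI.
    """
    if n_echoes < 1:
        raise ValueError("need at least 1 echo")
    if pe_direction not in (1, -1):
        raise ValueError("pe_direction must be +1 or -1")
    if n_pe % R:
        raise ValueError(f"n_pe={n_pe} not divisible by R={R}")
    P = n_pe // R
    seq = [(t % P, t // P) for t in range(P * n_echoes)]
    return _build(
        seq, n_pe, n_echoes, R, esp, P, te1, n_readout, pe_direction, "meepi", 1
    )


def _build(
    seq, n_pe, n_echoes, R, esp, dte_factor, te1,
    n_readout, pe_direction, style, n_classes,
) -> Trajectory:
    P = n_pe // R
    lines = []
    # Sign bookkeeping: the accrued off-resonance phase is +2*pi*b0*t, so
    # for a *positive* blip direction to displace features along +ky (the
    # standard EPI distortion statement), the ky index must descend with
    # time when pe_direction = +1.  The canonical assignment is built in
    # ascending p units and mirrored for pe_direction = +1.
    # the acquired ky lattice (stride R) is anchored so that it contains
    # the k-space center line floor(n_pe/2) -- the line that forms the echo
    anchor = (n_pe // 2) % R
    for t, (p, e) in enumerate(seq):
        if pe_direction == 1:
            p = P - 1 - p
        lines.append(TrajectoryLine(t=t, ky=p * R + anchor, echo=e))
    traj = Trajectory(
        n_pe=n_pe,
        n_readout=n_readout if n_readout is not None else n_pe,
        n_echoes=n_echoes,
        R=R,
        esp_ms=esp,
        dte_factor=dte_factor,
        lines=lines,
        te1_ms=te1,
        pe_direction=pe_direction,
        style=style,
        n_assignments=n_classes,
    )
    traj.te1_offset_ms = te1 - _center_cross_time(traj, 0) * esp
    return traj


def _center_cross_time(traj: Trajectory, echo: int) -> float:
    """Time index (fractional) at which an echo's line crosses ky center.

    The echo's samples are collinear in (t, ky); the crossing time of the
    fitted line at ky = floor(n_pe/2) anchors the echo time.
    """
    pts = [(ln.t, ln.ky) for ln in traj.lines if ln.echo == echo]
    pts.sort()
    (t0, ky0), (t1, ky1) = pts[0], pts[-1]
    center = traj.n_pe // 2
    if ky1 == ky0:  # single-line echo
        return float(t0)
    return t0 + (center - ky0) * (t1 - t0) / (ky1 - ky0)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def echo_times(traj: Trajectory) -> tuple[list[float], float]:
    """Nominal echo times (ms) and echo-time difference dTE (ms).

    ``TE_e = te1 + dte_factor * e * esp``; for me-EPI ``dte_factor`` is
    the per-image line count, giving the sequential-acquisition formula
    ``dTE = (n_pe / R) * esp``.
    """
    dte = traj.dte_factor * traj.esp_ms
    tes = [traj.te1_ms + e * dte for e in range(traj.n_echoes)]
    return tes, dte


def per_echo_sampling(traj: Trajectory):
    """Per-echo undersampling factor and per-echo binary ky masks.

    Returns ``(factor, masks)`` with ``masks`` an ``(n_echoes, n_pe)``
    boolean array: for rEPI the masks are disjoint and the factor is
    ``n_echoes * R``; for me-EPI the masks are identical and the factor
    is ``R``.
    """
    import numpy as np

    masks = np.zeros((traj.n_echoes, traj.n_pe), dtype=bool)
    for ln in traj.lines:
        masks[ln.echo, ln.ky] = True
    per_echo_lines = int(masks[0].sum())
    factor = traj.n_pe // per_echo_lines
    return factor, masks


def validate(traj: Trajectory) -> list[str]:
    """Diagnostic check of the rEPI design principles and invariants.

    Returns a list of human-readable violation messages; an empty list
    means the trajectory satisfies the complementary-lines principle,
    the equal-undersampling principle, consecutive time indexing and
    per-echo collinearity.  (A me-EPI trajectory deliberately violates
    complementarity -- its echoes resample the same lines -- and is
    reported as such.)
    """
    report: list[str] = []
    times = [ln.t for ln in traj.lines]
    if times != list(range(len(times))):
        report.append("time indices are not consecutive integers from 0")

    # complementarity: each ky at most once over the whole readout
    kys = [ln.ky for ln in traj.lines]
    if len(set(kys)) != len(kys):
        report.append("complementarity violated: ky line acquired more than once")

    # equal per-echo undersampling: constant stride n_echoes * R
    expected_stride = traj.n_echoes * traj.R
    for e in range(traj.n_echoes):
        ky_e = sorted(ln.ky for ln in traj.lines if ln.echo == e)
        if not ky_e:
            report.append(f"echo {e} has no lines")
            continue
        strides = {b - a for a, b in zip(ky_e, ky_e[1:])}
        if len(ky_e) > 1 and strides != {expected_stride}:
            report.append(
                f"equal undersampling violated: echo {e} ky stride(s) "
                f"{sorted(strides)} != {expected_stride}"
            )

    # collinearity of each echo's (t, ky) samples
    for e in range(traj.n_echoes):
        pts = sorted((ln.t, ln.ky) for ln in traj.lines if ln.echo == e)
        if len(pts) < 3:
            continue
        (t0, k0), (t1, k1) = pts[0], pts[-1]
        for t, k in pts[1:-1]:
            if (k - k0) * (t1 - t0) != (k1 - k0) * (t - t0):
                report.append(f"echo {e} samples are not collinear in ky-t")
                break
    return report
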
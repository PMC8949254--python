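"""Synthetic-data generator: pseudo-vectors, inserts, and noisy datasets.

The cloning experiments in this package run against synthetic circular
backbones with controlled restriction-site content (stand-ins for
proprietary commercial vectors), and the estimation routines are exercised
on forward-simulated dialysis/Job/inversion-recovery datasets with known
ground truth and Gaussian noise.  Everything is reproducible from
(kind, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .clonesim import REGISTRY, End, SeqMol, _find_sites
from .cds_designer import revcomp
from .gdbind import DialysisSetup, JobExperiment, job_curve, solve_dialysis_equilibrium
from .relaxometry import IRModel, PAPER_TI_GRID_MS, ir_signal

__all__ = [
    "FixtureSpec",
    "make_vector",
    "make_insert",
    "make_noisy_dataset",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind + parameters + mandatory seed."""

    kind: str  # "vector" | "insert" | "dialysis" | "job" | "ir_series"
    seed: int
    parameters: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("vector", "insert", "dialysis", "job", "ir_series"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _count_all_sites(seq: str, circular: bool = True) -> dict[str, int]:
    return {
        name: len(_find_sites(seq, enz, circular)) for name, enz in REGISTRY.items()
    }


def _scrub_sites(seq: str, rng: np.random.Generator, circular: bool = True) -> str:
    """Mutate single bases until no registry enzyme site remains."""
    seq_list = list(seq)
    for _ in range(10 * len(seq)):
        dirty = False
        for enz in REGISTRY.values():
            sites = _find_sites("".join(seq_list), enz, circular)
            for pos in sites:
                dirty = True
                hit = (pos + int(rng.integers(0, len(enz.recognition)))) % len(seq_list)
                old = seq_list[hit]
                seq_list[hit] = str(rng.choice([b for b in "ACGT" if b != old]))
        if not dirty:
            return "".join(seq_list)
    raise RuntimeError("could not scrub restriction sites")


def make_vector(
    length: int,
    unique_sites: tuple[str, ...] = ("BamHI",),
    seed: int = 0,
) -> SeqMol:
    """Random circular vector carrying each requested site exactly once.

    No other registry-enzyme site occurs anywhere in the backbone, so digests
    and ligations on fixture vectors are fully deterministic.
    """
    if length < 50 * (len(unique_sites) + 1):
        raise ValueError("vector too short for the requested site content")
    rng = np.random.default_rng(seed)
    for _ in range(50):
        backbone = _scrub_sites(_random_dna(rng, length), rng)
        # place sites at well-separated positions
        positions = sorted(
            rng.choice(
                np.arange(10, length - 10), size=len(unique_sites), replace=False
            )
        )
        if any(
            b - a < 20 for a, b in zip(positions, positions[1:])
        ):
            continue
        seq_list = list(backbone)
        for name, pos in zip(unique_sites, positions):
            site = REGISTRY[name].recognition
            seq_list[pos:pos + len(site)] = site
        candidate = "".join(seq_list)
        counts = _count_all_sites(candidate)
        want = {name: 1 for name in unique_sites}
        if all(counts[n] == want.get(n, 0) for n in counts):
            return SeqMol(candidate, topology="circular", name=f"synthetic-vector-{seed}")
    raise RuntimeError("failed to build a clean vector after bounded retries")


def make_insert(
    core_length: int = 60,
    left_enzyme: str = "BglII",
    right_enzyme: str = "BamHI",
    seed: int = 0,
) -> SeqMol:
    """Pre-digested insert flanked by the sticky ends of an isocaudomer pair.

    Returns the fragment exactly as the two enzymes would leave it: a left
    5' overhang from ``left_enzyme`` and a right end from ``right_enzyme``,
    with no internal registry sites.
    """
    rng = np.random.default_rng(seed)
    lz, rz = REGISTRY[left_enzyme], REGISTRY[right_enzyme]
    if lz.end_kind != "5ov" or rz.end_kind != "5ov":
        raise ValueError("insert flanks must be 5'-overhang cutters")
    core = _scrub_sites(_random_dna(rng, core_length), rng, circular=False)
    left_ovh = lz.recognition[lz.cut_top:lz.cut_bottom]
    right_site = rz.recognition
    # top strand: left overhang + post-overhang rest of left site + core +
    # right site up to the top cut
    top = (
        lz.recognition[lz.cut_top:]
        + core
        + right_site[:rz.cut_top]
    )
    right_ovh_top = right_site[rz.cut_top:rz.cut_bottom]
    return SeqMol(
        top,
        left_end=End("5ov", left_ovh),
        right_end=End("5ov", revcomp(right_ovh_top)),
        name=f"synthetic-insert-{seed}",
    )


def make_noisy_dataset(spec: FixtureSpec) -> dict:
    """Forward-simulate a named model with Gaussian noise + truth sidecar.

    Returns ``{"data": ..., "truth": ...}``; the data layout depends on the
    kind (dialysis: replicate free-Gd measurements; job: (x, complex)
    columns; ir_series: per-concentration (TI, SI) tables).
    """
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.parameters)

    if spec.kind == "dialysis":
        setup = DialysisSetup(
            site_total=p.get("site_total", 492.6),
            gd_total=p.get("gd_total", 492.6),
            kd=p["kd"],
            v_in=p.get("v_in", 2.0),
            v_out=p.get("v_out", 2.0),
        )
        state = solve_dialysis_equilibrium(setup)
        reps = int(p.get("replicates", 3))
        noise = float(p.get("noise", 0.02))
        measured = state.gd_free * (1.0 + noise * rng.standard_normal(reps))
        return {
            "data": {"gd_free_measured": measured.tolist()},
            "truth": {"kd": setup.kd, "gd_free": state.gd_free,
                      "setup": setup.__dict__},
        }

    if spec.kind == "job":
        n = int(p.get("n_points", 21))
        exp = JobExperiment(
            c_total=p.get("c_total", 50.0),
            kd=p.get("kd", 0.2),
            x_grid=tuple(np.linspace(0.0, 1.0, n)),
        )
        curve = job_curve(exp)
        noise = float(p.get("noise", 0.0))
        noisy = curve * (1.0 + noise * rng.standard_normal(curve.size))
        return {
            "data": {"x": list(exp.x_grid), "complex": noisy.tolist()},
            "truth": {"x_star": 0.5, "kd": exp.kd, "c_total": exp.c_total},
        }

    if spec.kind == "ir_series":
        t1 = float(p["t1"])
        ti = tuple(p.get("ti_grid", PAPER_TI_GRID_MS))
        model = IRModel(
            k=float(p.get("k", 1000.0)), t1=t1,
            tr=float(p.get("tr", 16000.0)), te=float(p.get("te", 7.1)),
            f=float(p.get("f", 180.0)),
        )
        si = np.asarray(ir_signal(model, ti))
        noise = float(p.get("noise", 0.0))
        si = si + noise * model.k * rng.standard_normal(si.size)
        return {
            "data": {"ti": list(ti), "si": si.tolist()},
            "truth": {"t1": t1, "k": model.k, "f": model.f},
        }

    if spec.kind == "vector":
        mol = make_vector(
            int(p.get("length", 3000)),
            tuple(p.get("unique_sites", ("BamHI",))),
            spec.seed,
        )
        return {"data": {"sequence": mol.seq, "topology": mol.topology},
                "truth": {"unique_sites": list(p.get("unique_sites", ("BamHI",)))}}

    if spec.kind == "insert":
        mol = make_insert(
            int(p.get("core_length", 60)),
            p.get("left_enzyme", "BglII"),
            p.get("right_enzyme", "BamHI"),
            spec.seed,
        )
        return {"data": {"sequence": mol.seq,
                         "left_ovh": mol.left_end.ovh,
                         "right_ovh": mol.right_end.ovh},
                "truth": {"flanks": [p.get("left_enzyme", "BglII"),
                                     p.get("right_enzyme", "BamHI")]}}

    raise ValueError(f"unknown fixture kind {spec.kind!r}")
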
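"""Synthetic CDS panels with known compositional and selectional structure.

The generator emulates the gross features of a vertebrate gene panel —
40–50 CDS of 150–3000 codons, per-gene GC3 spanning roughly 31–84%, a
neutrality relation tying GC12 to GC3, tunable codon-preference strength
and tunable CpG/TpA abundance — so that every analysis stage has inputs
whose ground truth is known.

Per gene the model is:

1. Draw a length and a GC3 target; derive a GC12 target from the
   neutrality line GC12 = m·GC3 + c + N(0, σ).
2. Give every codon a third-base weight (G/C-ending mass ``u`` against
   A/T-ending mass ``1−u``, the G-vs-C split tuned by a parameter γ),
   times a preference factor ``exp(κ)`` on one preferred codon per
   family, normalised within each synonymous family. ``u`` is calibrated
   by bisection so expected GC3 hits the target, and γ so that expected
   G3 = C3. κ = 0 gives pure compositional drift; large κ approaches
   one codon per family.
3. Tilt amino-acid frequencies exponentially along two directions,
   calibrated by bisection: each amino acid's expected position-1/2 G+C
   content to hit the GC12 target (positions 1/2 are fixed by the
   protein, so GC12 is steered through composition), and each family's
   expected A3 − T3 excess to restore the parity-rule-2 null A3 = T3 —
   the genetic code has six T/C-ending but only three A/G-ending
   two-fold families, so a uniform composition would sit off the PR2
   origin; balancing through composition rather than within-family
   weights keeps synonymous usage even and ENc at its drift value.
4. Sample the protein i.i.d. and codons per family. A
   ``cpg_suppression``/``tpa_suppression`` factor below 1 is a *target
   dinucleotide odds ratio*: synonymous codons are resampled with
   checkerboard Gibbs sweeps in which every CpG (TpA) occurrence —
   within codons and across codon boundaries — multiplies a codon's
   statistical weight by a factor, and that factor is iteratively
   corrected against the measured odds ratio so the realized ρ(CG),
   ρ(TA) land on the requested values. The protein is never changed.
   A factor of exactly 1 leaves codon choice i.i.d. (no shaping); the
   resulting natural ρ(CG) sits slightly below 1 because codon-position
   composition structure departs mildly from base independence.

A single ``numpy`` Generator seeded from ``seed`` drives all randomness;
panels are byte-reproducible for a fixed spec.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .genetic_code import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    CODON_TO_AA,
    DEGENERACY,
    STOP_CODONS,
)
from .sequence_io import CodingSequence

__all__ = [
    "SyntheticPanelSpec",
    "generate_panel",
    "generate_panel_with_truth",
    "default_preferred_codons",
    "write_truth",
]

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_A, _C, _G, _T = 0, 1, 2, 3


def default_preferred_codons() -> dict[str, str]:
    """One deterministic preferred codon per degenerate family.

    The G-ending codon with the highest G+C content, falling back to the
    C-ending one — a human-like C/G-ending preference (e.g. CTG for Leu).
    """
    prefs: dict[str, str] = {}
    for aa, codons in AA_TO_CODONS.items():
        if DEGENERACY[aa] < 2:
            continue
        ranked = sorted(
            codons,
            key=lambda c: (
                c[2] == "G",
                c[2] == "C",
                sum(b in "GC" for b in c),
                c,
            ),
            reverse=True,
        )
        prefs[aa] = ranked[0]
    return prefs


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Generative parameters for one panel. Defaults emulate the study
    conditions: 42 genes, 150–3000 codons, GC3 targets spanning 31–84%,
    a neutrality line with slope 0.27 and intercept 32 (percent) with
    Gaussian scatter, no codon preference, and dinucleotide odds ratios
    at their neutral value 1."""

    n_genes: int = 42
    length_codons_range: tuple[int, int] = (150, 3000)
    gc3_targets: Union[float, tuple[float, float], Sequence[float]] = (0.31, 0.84)
    bias_strength: float = 0.0
    preferred_codons: Mapping[str, str] | None = None
    cpg_suppression: float = 1.0
    tpa_suppression: float = 1.0
    neutrality_slope: float | None = 0.27
    neutrality_intercept: float = 32.0
    neutrality_noise_sd: float = 4.0
    amino_acid_freqs: Mapping[str, float] | None = None
    include_stop: bool = True
    gibbs_sweeps: int = 4
    calibrate_dinucleotides: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_codons_range
        if not (0 < lo <= hi):
            raise ValueError(f"empty length range {self.length_codons_range}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for name in ("cpg_suppression", "tpa_suppression"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if self.preferred_codons is not None:
            for aa, codon in self.preferred_codons.items():
                if CODON_TO_AA.get(codon) != aa:
                    raise ValueError(f"{codon} does not encode {aa}")


# ---------------------------------------------------------------------------
# family structure caches

_FAMILIES: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
for _aa in AMINO_ACIDS:
    _codons = AA_TO_CODONS[_aa]
    _third = np.array([_BASE_IDX[c[2]] for c in _codons])
    _gc12 = np.array([sum(b in "GC" for b in c[:2]) for c in _codons], dtype=float)
    _ids = np.array(
        [16 * _BASE_IDX[c[0]] + 4 * _BASE_IDX[c[1]] + _BASE_IDX[c[2]] for c in _codons]
    )
    _FAMILIES.append((_aa, _third, _gc12, _ids))

_N_FAM = len(_FAMILIES)

_CODON_OF_ID = [""] * 64
for _c in list(CODON_TO_AA) + list(STOP_CODONS):
    _CODON_OF_ID[16 * _BASE_IDX[_c[0]] + 4 * _BASE_IDX[_c[1]] + _BASE_IDX[_c[2]]] = _c

_FIRST = np.arange(64) // 16
_LAST = np.arange(64) % 4
_MID = (np.arange(64) // 4) % 4
_WITHIN_CG = ((_FIRST == _C) & (_MID == _G)).astype(int) + (
    (_MID == _C) & (_LAST == _G)
).astype(int)
_WITHIN_TA = ((_FIRST == _T) & (_MID == _A)).astype(int) + (
    (_MID == _T) & (_LAST == _A)
).astype(int)


def _family_probs(
    u: float, alpha: float, gamma: float, kappa: float, prefs: Mapping[str, str]
) -> list[np.ndarray]:
    """Within-family codon probabilities.

    Third-base masses: A gets (1−u)·2α, T gets (1−u)·2(1−α), G gets
    u·2γ, C gets u·2(1−γ); α = γ = 0.5 splits each side evenly.
    """
    mass = np.array(
        [
            2.0 * (1.0 - u) * alpha,  # A
            2.0 * u * (1.0 - gamma),  # C
            2.0 * u * gamma,  # G
            2.0 * (1.0 - u) * (1.0 - alpha),  # T
        ]
    )
    out = []
    for aa, third, _gc12, ids in _FAMILIES:
        w = mass[third]
        if kappa > 0 and aa in prefs:
            pref_mask = np.array(
                [_CODON_OF_ID[i] == prefs[aa] for i in ids], dtype=float
            )
            w = w * np.exp(kappa * pref_mask)
        total = w.sum()
        if total <= 0:  # all-available bases zeroed by extreme parameters
            w = mass[third] + 1e-12
            total = w.sum()
        out.append(w / total)
    return out


def _third_base_expectations(
    aa_probs: np.ndarray, fam_probs: list[np.ndarray]
) -> np.ndarray:
    """Expected per-codon third-base distribution (A, C, G, T)."""
    e = np.zeros(4)
    for i in range(_N_FAM):
        third = _FAMILIES[i][1]
        for b in range(4):
            e[b] += aa_probs[i] * float(fam_probs[i][third == b].sum())
    return e


def _gc12_per_aa(fam_probs: list[np.ndarray]) -> np.ndarray:
    return np.array(
        [float(fam_probs[i] @ _FAMILIES[i][2]) / 2.0 for i in range(_N_FAM)]
    )


def _bisect(func, lo: float, hi: float, target: float, tol: float = 1e-7) -> float:
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if func(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _calibrate_gene(
    gc3_target: float,
    gc12_target: float | None,
    kappa: float,
    prefs: Mapping[str, str],
    base_aa: np.ndarray,
) -> tuple[np.ndarray, list[np.ndarray], float | None]:
    """Solve (u, α, γ, amino-acid tilt) for the gene's targets.

    Returns amino-acid probabilities, family codon probabilities, and
    the achievable GC12 expectation (None when no GC12 target given).
    """
    alpha = 0.5  # within-family A/T split stays even, protecting ENc
    gamma = 0.5
    theta = psi = 0.0
    achieved_gc12: float | None = None
    u = 0.5
    aa_probs = base_aa.copy()
    fam_probs = _family_probs(u, alpha, gamma, kappa, prefs)

    def tilt_aa(th: float, ps: float, g12: np.ndarray, dat: np.ndarray) -> np.ndarray:
        p = base_aa * np.exp(th * g12 + ps * dat)
        return p / p.sum()

    for _round in range(3):

        def e_gc3(v: float) -> float:
            e = _third_base_expectations(aa_probs, _family_probs(v, alpha, gamma, kappa, prefs))
            return e[_C] + e[_G]

        lo_val, hi_val = e_gc3(0.0), e_gc3(1.0)
        if not lo_val - 1e-9 <= gc3_target <= hi_val + 1e-9:
            raise ValueError(
                f"gc3 target {gc3_target:.3f} infeasible: achievable range "
                f"[{lo_val:.3f}, {hi_val:.3f}] under bias_strength={kappa}, "
                f"preferred_codons={dict(prefs) if prefs else None}, "
                f"amino_acid_freqs as given"
            )
        u = _bisect(e_gc3, 0.0, 1.0, float(np.clip(gc3_target, lo_val, hi_val)))
        fam_probs = _family_probs(u, alpha, gamma, kappa, prefs)

        # parity-rule-2 null, A3 = T3: tilt the amino-acid composition
        # along each family's A3−T3 excess (the genetic code has six
        # T/C-ending but only three A/G-ending two-fold families, so a
        # uniform composition sits off the PR2 origin); tilting the
        # composition rather than the within-family split leaves
        # synonymous usage even and ENc unaffected.
        g12 = _gc12_per_aa(fam_probs)
        dat = np.array(
            [
                float(fam_probs[i][_FAMILIES[i][1] == _A].sum())
                - float(fam_probs[i][_FAMILIES[i][1] == _T].sum())
                for i in range(_N_FAM)
            ]
        )

        def at_diff(ps: float) -> float:
            return float(tilt_aa(theta, ps, g12, dat) @ dat)

        if at_diff(-20.0) < 0.0 < at_diff(20.0):
            psi = _bisect(at_diff, -20.0, 20.0, 0.0)
        aa_probs = tilt_aa(theta, psi, g12, dat)

        # G3 = C3 through the within-family G/C split; the required shift
        # off 0.5 is small (Met/Trp contribute fixed G3) so the cost in
        # synonymous-usage evenness is negligible.
        def gc_diff(g: float) -> float:
            e = _third_base_expectations(
                aa_probs, _family_probs(u, alpha, g, kappa, prefs)
            )
            return e[_G] - e[_C]

        if gc_diff(0.0) < 0.0 < gc_diff(1.0):
            gamma = _bisect(gc_diff, 0.0, 1.0, 0.0)
        fam_probs = _family_probs(u, alpha, gamma, kappa, prefs)

        if gc12_target is None:
            continue
        g12 = _gc12_per_aa(fam_probs)

        def exp_gc12(th: float) -> float:
            return float(tilt_aa(th, psi, g12, dat) @ g12)

        lo_g, hi_g = exp_gc12(-40.0), exp_gc12(40.0)
        clipped = float(np.clip(gc12_target, lo_g + 1e-9, hi_g - 1e-9))
        theta = _bisect(exp_gc12, -40.0, 40.0, clipped)
        aa_probs = tilt_aa(theta, psi, g12, dat)
        achieved_gc12 = float(aa_probs @ g12)
    return aa_probs, fam_probs, achieved_gc12


# ---------------------------------------------------------------------------
# sampling


def _sample_codons(
    aa_idx: np.ndarray,
    fam_probs: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    codon_ids = np.empty(aa_idx.size, dtype=np.int64)
    for fi in range(_N_FAM):
        mask = aa_idx == fi
        n = int(mask.sum())
        if n == 0:
            continue
        ids = _FAMILIES[fi][3]
        picks = rng.choice(ids.size, size=n, p=fam_probs[fi])
        codon_ids[mask] = ids[picks]
    return codon_ids


def _bases_of(codon_ids: np.ndarray) -> np.ndarray:
    b = np.empty(3 * codon_ids.size, dtype=np.int64)
    b[0::3] = _FIRST[codon_ids]
    b[1::3] = _MID[codon_ids]
    b[2::3] = _LAST[codon_ids]
    return b


def _measure_rho(codon_ids: np.ndarray) -> tuple[float, float]:
    """Observed CG and TA odds ratios of the codon sequence."""
    b = _bases_of(codon_ids)
    n = b.size
    mono = np.bincount(b, minlength=4) / n
    x, y = b[:-1], b[1:]
    f_cg = np.sum((x == _C) & (y == _G)) / (n - 1)
    f_ta = np.sum((x == _T) & (y == _A)) / (n - 1)
    rho_cg = f_cg / (mono[_C] * mono[_G]) if mono[_C] * mono[_G] > 0 else np.nan
    rho_ta = f_ta / (mono[_T] * mono[_A]) if mono[_T] * mono[_A] > 0 else np.nan
    return float(rho_cg), float(rho_ta)


def _gibbs_sweeps(
    codon_ids: np.ndarray,
    aa_idx: np.ndarray,
    fam_probs: list[np.ndarray],
    t_cg: float,
    t_ta: float,
    sweeps: int,
    rng: np.random.Generator,
) -> None:
    """Checkerboard Gibbs resampling of synonymous codons with CpG/TpA
    occurrence factors, in place. Codons at even (odd) positions are
    conditionally independent given the other parity, so each half-sweep
    is an exact Gibbs update."""
    L = codon_ids.size
    pos_all = np.arange(L)
    for _ in range(sweeps):
        for parity in (0, 1):
            for fi in range(_N_FAM):
                ids = _FAMILIES[fi][3]
                if ids.size < 2:
                    continue
                pos = pos_all[(aa_idx == fi) & (pos_all % 2 == parity)]
                if pos.size == 0:
                    continue
                prev_last = np.where(
                    pos > 0, _LAST[codon_ids[np.maximum(pos - 1, 0)]], -1
                )
                next_first = np.where(
                    pos < L - 1, _FIRST[codon_ids[np.minimum(pos + 1, L - 1)]], -1
                )
                cand_first = _FIRST[ids][None, :]
                cand_last = _LAST[ids][None, :]
                n_cg = (
                    _WITHIN_CG[ids][None, :]
                    + ((prev_last[:, None] == _C) & (cand_first == _G))
                    + ((cand_last == _C) & (next_first[:, None] == _G))
                )
                n_ta = (
                    _WITHIN_TA[ids][None, :]
                    + ((prev_last[:, None] == _T) & (cand_first == _A))
                    + ((cand_last == _T) & (next_first[:, None] == _A))
                )
                w = fam_probs[fi][None, :] * (t_cg ** n_cg) * (t_ta ** n_ta)
                w /= w.sum(axis=1, keepdims=True)
                cum = np.cumsum(w, axis=1)
                choice = (rng.random(pos.size)[:, None] > cum).sum(axis=1)
                codon_ids[pos] = ids[choice]


def _shape_dinucleotides(
    codon_ids: np.ndarray,
    aa_idx: np.ndarray,
    fam_probs: list[np.ndarray],
    rho_cg_target: float,
    rho_ta_target: float,
    sweeps: int,
    rng: np.random.Generator,
) -> None:
    """Drive realized ρ(CG), ρ(TA) toward the targets.

    The Gibbs factor per occurrence does not map one-to-one onto the
    realized odds ratio (suppressing CpG also depletes C and G, which
    feeds back through the denominator), so each factor is corrected
    multiplicatively against the measured ratio between rounds. A factor
    of exactly 1 is a no-op channel: it is never corrected, so the
    corresponding dinucleotide keeps its natural codon-structure odds.
    """
    shape_cg = rho_cg_target < 1.0
    shape_ta = rho_ta_target < 1.0
    t_cg = rho_cg_target if shape_cg else 1.0
    t_ta = rho_ta_target if shape_ta else 1.0
    n_rounds = 5
    for round_i in range(n_rounds):
        n_sweeps = sweeps if round_i == 0 else max(2, sweeps // 2)
        _gibbs_sweeps(codon_ids, aa_idx, fam_probs, t_cg, t_ta, n_sweeps, rng)
        if round_i == n_rounds - 1:
            break
        rho_cg, rho_ta = _measure_rho(codon_ids)
        if shape_cg and np.isfinite(rho_cg) and rho_cg > 0:
            t_cg = float(np.clip(t_cg * rho_cg_target / rho_cg, 1e-4, 1e4))
        if shape_ta and np.isfinite(rho_ta) and rho_ta > 0:
            t_ta = float(np.clip(t_ta * rho_ta_target / rho_ta, 1e-4, 1e4))


def _resolve_gc3_targets(
    spec: SyntheticPanelSpec, rng: np.random.Generator
) -> np.ndarray:
    t = spec.gc3_targets
    if isinstance(t, (int, float)):
        return np.full(spec.n_genes, float(t))
    t = np.asarray(t, dtype=float)
    if t.size == 2 and spec.n_genes != 2:
        return rng.uniform(t[0], t[1], size=spec.n_genes)
    if t.size != spec.n_genes:
        raise ValueError("gc3_targets length does not match n_genes")
    return t


def generate_panel_with_truth(
    spec: SyntheticPanelSpec,
) -> tuple[list[CodingSequence], dict]:
    """Generate a panel plus a ground-truth record for recovery tests."""
    rng = np.random.default_rng(spec.seed)
    prefs = (
        dict(spec.preferred_codons)
        if spec.preferred_codons is not None
        else default_preferred_codons()
    )
    if spec.amino_acid_freqs is None:
        base_aa = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    else:
        base_aa = np.array(
            [spec.amino_acid_freqs.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float
        )
        if base_aa.sum() <= 0:
            raise ValueError("amino_acid_freqs sum to zero")
        base_aa = base_aa / base_aa.sum()

    gc3_targets = _resolve_gc3_targets(spec, rng)
    lo, hi = spec.length_codons_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)

    panel: list[CodingSequence] = []
    gene_truth = []
    stop_list = sorted(STOP_CODONS)
    for i in range(spec.n_genes):
        # per-gene substream: gene i's draws are independent of how much
        # randomness other genes or the Gibbs stage consumed
        grng = np.random.default_rng([spec.seed, i])
        t = float(gc3_targets[i])
        if spec.neutrality_slope is None:
            gc12_target = None
        else:
            noise = grng.normal(0.0, spec.neutrality_noise_sd)
            gc12_target = (
                spec.neutrality_slope * (t * 100.0)
                + spec.neutrality_intercept
                + noise
            ) / 100.0
        aa_probs, fam_probs, achieved_gc12 = _calibrate_gene(
            t, gc12_target, spec.bias_strength, prefs, base_aa
        )
        L = int(lengths[i])
        aa_idx = grng.choice(len(AMINO_ACIDS), size=L, p=aa_probs)
        codon_ids = _sample_codons(aa_idx, fam_probs, grng)
        if spec.calibrate_dinucleotides and (
            spec.cpg_suppression < 1.0 or spec.tpa_suppression < 1.0
        ):
            _shape_dinucleotides(
                codon_ids,
                aa_idx,
                fam_probs,
                spec.cpg_suppression,
                spec.tpa_suppression,
                spec.gibbs_sweeps,
                grng,
            )
        seq = "".join(_CODON_OF_ID[c] for c in codon_ids)
        if spec.include_stop:
            seq += stop_list[grng.integers(len(stop_list))]
        gene_id = f"syn{i + 1:03d}"
        cds = CodingSequence(gene_id, seq)
        n_codons = len(seq) // 3
        realized_gc3 = (
            100.0 * sum(b in "GC" for b in seq[2::3]) / n_codons
        )
        gc1 = 100.0 * sum(b in "GC" for b in seq[0::3]) / n_codons
        gc2 = 100.0 * sum(b in "GC" for b in seq[1::3]) / n_codons
        rho_cg, rho_ta = _measure_rho(codon_ids)
        panel.append(cds)
        gene_truth.append(
            {
                "gene_id": gene_id,
                "length_codons": L,
                "gc3_target": t,
                "gc12_target": gc12_target,
                "gc12_achievable": achieved_gc12,
                "realized_gc3": realized_gc3,
                "realized_gc12": (gc1 + gc2) / 2.0,
                "realized_rho_cg": rho_cg,
                "realized_rho_ta": rho_ta,
            }
        )

    truth = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
            if k not in ("preferred_codons", "amino_acid_freqs", "gc3_targets")
        },
        "preferred_codons": prefs,
        "genes": gene_truth,
    }
    return panel, truth


def generate_panel(spec: SyntheticPanelSpec) -> list[CodingSequence]:
    panel, _ = generate_panel_with_truth(spec)
    return panel


def write_truth(truth: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
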
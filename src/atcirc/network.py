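"""circRNA-miRNA-mRNA sponge networks and absolute copy numbers.

Canonical miRNA sites (8mer, 7mer-m8, 7mer-A1) are scanned on full-length
circRNA sequences; because the molecule is circular, the doubled sequence is
scanned so sites straddling the back-splice junction are found and flagged.
A miRNA's regulatory footprint is tested by comparing differentiation
log2 fold changes of its top predicted mRNA targets (context++ score in the
top decile) against an equal-size random draw of genes without a site; a
significant mRNA shift without a pre-mRNA shift marks post-transcriptional
regulation, the signature of sponge-mediated control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bsj import nearest_rank_quantile
from .sequences import revcomp

AVOGADRO = 6.02214e23
DSDNA_G_PER_MOL_PER_BP = 617.96


@dataclass(frozen=True)
class MiRNASite:
    region_id: str
    mirna_id: str
    site_class: str  # '8mer' | '7mer-m8' | '7mer-A1'
    start: int  # on the (linearized) circular sequence, 0-based
    end: int
    spans_bsj: bool


def scan_mirna_sites(
    sequence: str,
    mirna_id: str,
    mature_seq: str,
    region_id: str = "",
    circular: bool = True,
) -> list[MiRNASite]:
    """Canonical seed-site scan on the sense sequence.

    Site classes follow the standard definitions: the target carries the
    reverse complement of miRNA positions 2-7 (the 6mer core), optionally
    extended by a position-8 match (m8) and/or an adenosine opposite
    position 1 (A1).  8mer = m8 + A1; 7mer-m8 = m8 only; 7mer-A1 = A1 only.
    For circular regions the doubled sequence is scanned and duplicate sites
    (start >= length) removed, so junction-spanning sites are captured.
    """
    mature = mature_seq.upper().replace("U", "T")
    if len(mature) < 8:
        raise ValueError(f"{mirna_id}: mature sequence shorter than 8 nt (seed undefined)")
    core = revcomp(mature[1:7])  # pairs miRNA positions 2-7
    m8 = revcomp(mature[7])  # pairs position 8
    seq = sequence.upper().replace("U", "T")
    L = len(seq)
    scan_seq = seq + seq if circular else seq
    sites = []
    p = scan_seq.find(core)
    while p != -1:
        has_m8 = p >= 1 and scan_seq[p - 1] == m8
        has_a1 = p + 6 < len(scan_seq) and scan_seq[p + 6] == "A"
        cls = start = end = None
        if has_m8 and has_a1:
            cls, start, end = "8mer", p - 1, p + 7
        elif has_m8:
            cls, start, end = "7mer-m8", p - 1, p + 6
        elif has_a1:
            cls, start, end = "7mer-A1", p, p + 7
        if cls is not None and start < L:
            sites.append(
                MiRNASite(
                    region_id, mirna_id, cls, start, end,
                    spans_bsj=bool(circular and end > L),
                )
            )
        p = scan_seq.find(core, p + 1)
    return sites


# ------------------------------------------------------------ shift test


@dataclass(frozen=True)
class TargetShiftResult:
    mirna_id: str
    n_top_targets: int
    mean_log2fc_targets: float
    mean_log2fc_random: float
    p_value: float
    p_value_pre: Optional[float]
    rng_seed: int
    testable: bool = True


def _two_group_t(x: np.ndarray, y: np.ndarray) -> float:
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def top_targets(
    context_scores: pd.DataFrame, mirna_id: str, percentile: float = 0.90
) -> list[str]:
    """Genes whose predicted repression strength ranks strictly above the
    inclusive empirical ``percentile`` within this miRNA's target list.

    ``context_scores`` needs columns gene_id, mirna_id, score; context++
    scores are more negative for stronger predicted repression, so ranking
    is on -score.
    """
    sub = context_scores[context_scores["mirna_id"] == mirna_id]
    if sub.empty:
        return []
    strength = -sub["score"].to_numpy(dtype=float)
    thr = nearest_rank_quantile(strength, percentile)
    return sorted(sub.loc[strength > thr, "gene_id"])


def target_shift_test(
    log2fc: pd.Series,
    context_scores: pd.DataFrame,
    mirna_id: str,
    percentile: float = 0.90,
    rng_seed: int = 0,
    pre_log2fc: Optional[pd.Series] = None,
    min_targets: int = 10,
) -> TargetShiftResult:
    """Compare log2 fold changes of a miRNA's top targets vs random non-targets.

    The control set is an equal-size seeded uniform draw from genes present
    in the expression table with no annotated site for this miRNA.  The same
    comparison is repeated on pre-mRNA fold changes when supplied (a
    non-significant pre-mRNA shift places the regulation downstream of
    transcription).
    """
    tops = [g for g in top_targets(context_scores, mirna_id, percentile) if g in log2fc.index]
    all_targets = set(context_scores.loc[context_scores["mirna_id"] == mirna_id, "gene_id"])
    universe = [g for g in log2fc.index if g not in all_targets]
    if len(tops) < min_targets or len(universe) < len(tops):
        return TargetShiftResult(
            mirna_id, len(tops), float("nan"), float("nan"), float("nan"),
            None, rng_seed, testable=False,
        )
    rng = np.random.default_rng(rng_seed)
    controls = list(rng.choice(universe, size=len(tops), replace=False))
    x = log2fc.loc[tops].to_numpy(dtype=float)
    y = log2fc.loc[controls].to_numpy(dtype=float)
    p = _two_group_t(x, y)
    p_pre = None
    if pre_log2fc is not None:
        tops_pre = [g for g in tops if g in pre_log2fc.index]
        ctrl_pre = [g for g in controls if g in pre_log2fc.index]
        if len(tops_pre) >= min_targets and len(ctrl_pre) >= min_targets:
            p_pre = _two_group_t(
                pre_log2fc.loc[tops_pre].to_numpy(dtype=float),
                pre_log2fc.loc[ctrl_pre].to_numpy(dtype=float),
            )
    return TargetShiftResult(
        mirna_id, len(tops), float(np.mean(x)), float(np.mean(y)), p, p_pre, rng_seed
    )


# ---------------------------------------------------------------- network


@dataclass(frozen=True)
class NetworkEdge:
    circ_id: str
    mirna_id: str
    site_count: int
    spans_bsj_sites: int
    circ_log2fc: float
    circ_significant: bool
    mirna_log2fc: float
    mirna_significant: bool
    target_shift_p: float
    target_shift_direction: str  # 'up' | 'down' | 'none'
    consistency: str  # 'sponge_consistent_release' | 'sponge_consistent_reinforcing' | 'unsupported'


def build_network(
    sites: Sequence[MiRNASite],
    shifts: Mapping[str, TargetShiftResult],
    circ_de: Mapping[str, tuple[float, bool]],
    mirna_de: Mapping[str, tuple[float, bool]],
    alpha: float = 0.05,
) -> list[NetworkEdge]:
    """Assemble circRNA->miRNA->target edges and label sponge consistency.

    A sponge model predicts that the sign of the circRNA change propagates
    to its miRNA's targets (circ down -> miRNA released -> targets down;
    circ up -> miRNA sequestered -> targets up).  The label is
    'release' when the miRNA itself is flat, 'reinforcing' when the miRNA
    also moves opposite to the circRNA, 'unsupported' otherwise.
    """
    by_pair: dict[tuple[str, str], list[MiRNASite]] = {}
    for s in sites:
        by_pair.setdefault((s.region_id, s.mirna_id), []).append(s)
    edges = []
    for (circ_id, mirna_id), pair_sites in sorted(by_pair.items()):
        shift = shifts.get(mirna_id)
        circ_fc, circ_sig = circ_de.get(circ_id, (0.0, False))
        mir_fc, mir_sig = mirna_de.get(mirna_id, (0.0, False))
        if shift is not None and shift.testable and shift.p_value < alpha:
            t_dir = "down" if shift.mean_log2fc_targets < shift.mean_log2fc_random else "up"
        else:
            t_dir = "none"
        consistency = "unsupported"
        signs_agree = t_dir != "none" and circ_sig and (
            (circ_fc < 0 and t_dir == "down") or (circ_fc > 0 and t_dir == "up")
        )
        if signs_agree and not mir_sig:
            consistency = "sponge_consistent_release"
        elif signs_agree and mir_sig and np.sign(mir_fc) == -np.sign(circ_fc):
            consistency = "sponge_consistent_reinforcing"
        edges.append(
            NetworkEdge(
                circ_id,
                mirna_id,
                len(pair_sites),
                sum(s.spans_bsj for s in pair_sites),
                circ_fc,
                circ_sig,
                mir_fc,
                mir_sig,
                shift.p_value if shift is not None and shift.testable else float("nan"),
                t_dir,
                consistency,
            )
        )
    return edges


# ------------------------------------------------------------ copy number


@dataclass
class CopyNumberInput:
    """Inputs of the template copy-number equation copies = c*V*Na/M."""

    concentration_g_per_ul: float
    volume_ul: float
    molar_mass_g_per_mol: float
    avogadro: float = AVOGADRO
    standard_curve: Optional[Sequence[tuple[float, float]]] = None  # (Ct, log2 copies)
    sample_ct: Optional[float] = None
    n_cells: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.concentration_g_per_ul, self.volume_ul, self.molar_mass_g_per_mol) <= 0:
            raise ValueError("c, V and M must be positive")


def template_molar_mass(sequence: str, g_per_mol_per_bp: float = DSDNA_G_PER_MOL_PER_BP) -> float:
    """Average double-stranded template molar mass from its length."""
    if not sequence:
        raise ValueError("empty template sequence")
    return len(sequence) * g_per_mol_per_bp


def template_copies(inp: CopyNumberInput) -> float:
    """copies = c x V x Na / M."""
    return (
        inp.concentration_g_per_ul * inp.volume_ul * inp.avogadro
        / inp.molar_mass_g_per_mol
    )


def estimate_copies(
    inp: CopyNumberInput,
    normalized_rc: Mapping[str, float],
    reference_circ: str,
) -> pd.Series:
    """Per-circRNA copies extrapolated from one absolutely quantified circRNA.

    The reference copy number comes from the template equation; when a
    standard curve (Ct vs log2 copies) and a sample Ct are supplied, the
    per-cell reference is read off the fitted line and divided by the cell
    count.  Every other circRNA scales linearly by its normalized read
    count: copies_i = copies_ref * normRC_i / normRC_ref.
    """
    norm_ref = normalized_rc.get(reference_circ, 0.0)
    if norm_ref <= 0:
        raise ValueError(f"reference circRNA {reference_circ!r} has nonpositive normalized RC")
    if inp.standard_curve is not None and inp.sample_ct is not None:
        ct = np.array([c for c, _ in inp.standard_curve], dtype=float)
        logc = np.array([l for _, l in inp.standard_curve], dtype=float)
        slope, intercept = np.polyfit(ct, logc, 1)
        copies_ref = 2.0 ** (slope * inp.sample_ct + intercept)
        if inp.n_cells:
            copies_ref /= inp.n_cells
    else:
        copies_ref = template_copies(inp)
        if inp.n_cells:
            copies_ref /= inp.n_cells
    out = {
        circ: copies_ref * v / norm_ref for circ, v in normalized_rc.items()
    }
    return pd.Series(out).sort_index()
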
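"""Published per-system reference values for Pin1-catalyzed prolyl isomerization.

Summary rows (activation free energies, cis-trans free-energy difference,
trans->cis rate constant and, for the unmodified potential, the effective
diffusion coefficient) for six peptide / Pin1-construct systems, at several
scaled barrier amplitudes alpha and at the real dihedral amplitude
V2 = 28 kcal/mol.  These serve as inputs to the comparative reporting layer
(differences with propagated errors, fold changes); the package does not
regenerate them.

Systems: FFSPR and FFpSPR free in solution; FFpSPR bound to the catalytic
(PPIase) domain alone; to full-length Pin1 with an empty WW domain; and to
full-length Pin1 with FFpSPR or pTPP occupying the WW domain.
"""

from __future__ import annotations

from typing import Dict, List

from .report_cli import SummaryRow, SystemSummary
from .uncertainty import Measurement as M

# rows: (alpha, V2, dG#_tc, dG#_ct, dG_cis-trans, k_tc, D_eff or None)
_ROWS = {
    "FFSPR": [
        (0.25, 7.0, (4.33, 0.07), (2.93, 0.11), (1.40, 0.09), (7.72e7, 0.70e7), None),
        (0.30, 8.4, (5.28, 0.05), (3.85, 0.10), (1.43, 0.10), (2.55e7, 0.07e7), None),
        (0.35, 9.8, (6.72, 0.05), (4.98, 0.09), (1.74, 0.08), (5.02e6, 0.07e6), None),
        (1.00, 28.0, (23.50, 0.47), (20.39, 0.51), (3.11, 0.45), (1.08e-5, 0.17e-5),
         (4.50e14, 0.72e14)),
    ],
    "FFpSPR": [
        (0.25, 7.0, (4.02, 0.06), (2.45, 0.10), (1.57, 0.08), (4.15e7, 0.12e7), None),
        (0.30, 8.4, (5.25, 0.07), (3.60, 0.10), (1.65, 0.07), (1.75e7, 0.03e7), None),
        (0.35, 9.8, (6.55, 0.06), (4.66, 0.10), (1.90, 0.09), (1.23e7, 0.04e7), None),
        (1.00, 28.0, (24.47, 0.58), (21.24, 0.52), (3.23, 0.60), (6.29e-7, 3.68e-7),
         (1.11e14, 0.65e14)),
    ],
    "FFpSPR-PPIase": [
        (0.35, 9.8, (3.20, 0.10), (0.62, 0.13), (2.57, 0.11), (7.90e6, 0.24e6), None),
        (0.40, 11.2, (3.88, 0.05), (1.13, 0.07), (2.75, 0.06), (5.13e6, 0.08e6), None),
        (0.45, 12.6, (5.67, 0.13), (2.12, 0.16), (3.55, 0.10), (1.91e6, 0.01e6), None),
        (1.00, 28.0, (16.60, 0.03), (14.16, 0.07), (2.45, 0.07), (4.07e-2, 2.21e-2),
         (1.66e13, 0.90e13)),
    ],
    "FFpSPR-Pin1": [
        (0.43, 12.0, (3.13, 0.12), (0.91, 0.15), (2.22, 0.10), (7.45e7, 2.50e7), None),
        (0.45, 12.6, (4.79, 0.03), (0.58, 0.05), (4.21, 0.04), (1.94e7, 0.14e7), None),
        (0.50, 14.0, (5.41, 0.05), (2.85, 0.07), (2.56, 0.05), (7.37e6, 0.45e6), None),
        (1.00, 28.0, (16.08, 0.12), (13.63, 0.16), (2.45, 0.12), (2.30e-1, 0.39e-1),
         (4.99e13, 0.84e13)),
    ],
    "FFpSPR-FFpSPR": [
        (0.35, 9.8, (3.20, 0.08), (0.20, 0.12), (3.00, 0.09), (1.09e7, 0.02e7), None),
        (0.40, 11.2, (4.24, 0.09), (0.17, 0.13), (4.07, 0.09), (6.70e6, 0.09e6), None),
        (0.45, 12.6, (5.52, 0.05), (0.06, 0.08), (5.47, 0.07), (7.79e6, 0.10e6), None),
        (1.00, 28.0, (16.90, 0.08), (12.60, 0.12), (4.28, 0.10), (1.46e-2, 1.28e-2),
         (1.00e13, 0.88e13)),
    ],
    "FFpSPR-pTPP": [
        (0.43, 12.0, (4.34, 0.07), (1.08, 0.10), (3.27, 0.07), (3.97e7, 0.54e7), None),
        (0.45, 12.6, (3.78, 0.07), (1.25, 0.11), (2.53, 0.08), (5.17e6, 0.05e6), None),
        (0.50, 14.0, (4.85, 0.07), (2.36, 0.10), (2.49, 0.08), (3.46e6, 0.03e6), None),
        (1.00, 28.0, (15.46, 0.04), (13.07, 0.06), (2.39, 0.05), (1.05e-1, 0.24e-1),
         (6.51e12, 1.47e12)),
    ],
}

# free peptides: full-barrier free energies and rates from the extrapolation
# scheme; complexes: free energies sampled directly at the real potential,
# rates from extrapolation
_PROVENANCE = {
    "FFSPR": "extrapolated",
    "FFpSPR": "extrapolated",
    "FFpSPR-PPIase": "direct",
    "FFpSPR-Pin1": "direct",
    "FFpSPR-FFpSPR": "direct",
    "FFpSPR-pTPP": "direct",
}

SYSTEM_ORDER = tuple(_ROWS)


def reference_summaries() -> Dict[str, SystemSummary]:
    """The six reference systems as :class:`SystemSummary` objects."""
    out = {}
    for name, rows in _ROWS.items():
        summary_rows: List[SummaryRow] = []
        for alpha, v2, tc, ct, dct, k, deff in rows:
            summary_rows.append(
                SummaryRow(
                    alpha=alpha, v2=v2,
                    dg_tc=M(*tc), dg_ct=M(*ct), dg_cis_trans=M(*dct), k=M(*k),
                    d_eff=M(*deff) if deff is not None else None,
                )
            )
        out[name] = SystemSummary(
            system=name, rows=summary_rows, provenance=_PROVENANCE[name]
        )
    return out


#: comparative statements computed from the real-potential rows
DEFAULT_COMPARISON_PLAN = [
    {"name": "phospho_dg_tc_increase_kcal", "kind": "delta", "quantity": "dg_tc",
     "a": "FFpSPR", "b": "FFSPR"},
    {"name": "phospho_dg_ct_increase_kcal", "kind": "delta", "quantity": "dg_ct",
     "a": "FFpSPR", "b": "FFSPR"},
    {"name": "ppiase_dg_tc_reduction_kcal", "kind": "delta", "quantity": "dg_tc",
     "a": "FFpSPR", "b": "FFpSPR-PPIase"},
    {"name": "ww_addition_dg_tc_reduction_kcal", "kind": "delta", "quantity": "dg_tc",
     "a": "FFpSPR-PPIase", "b": "FFpSPR-Pin1"},
    {"name": "ww_addition_rate_fold", "kind": "fold", "quantity": "k",
     "a": "FFpSPR-Pin1", "b": "FFpSPR-PPIase"},
    {"name": "ww_ligand_dg_cis_trans_increase_kcal", "kind": "delta",
     "quantity": "dg_cis_trans", "a": "FFpSPR-FFpSPR", "b": "FFpSPR"},
    {"name": "ww_ligand_dg_tc_increase_kcal", "kind": "delta", "quantity": "dg_tc",
     "a": "FFpSPR-FFpSPR", "b": "FFpSPR-Pin1"},
    {"name": "ww_ligand_dg_ct_reduction_kcal", "kind": "delta", "quantity": "dg_ct",
     "a": "FFpSPR-Pin1", "b": "FFpSPR-FFpSPR"},
    {"name": "ww_ligand_rate_fold_reduction", "kind": "fold", "quantity": "k",
     "a": "FFpSPR-Pin1", "b": "FFpSPR-FFpSPR"},
    {"name": "ptpp_dg_tc_reduction_kcal", "kind": "delta", "quantity": "dg_tc",
     "a": "FFpSPR-Pin1", "b": "FFpSPR-pTPP"},
    {"name": "ptpp_dg_ct_reduction_kcal", "kind": "delta", "quantity": "dg_ct",
     "a": "FFpSPR-Pin1", "b": "FFpSPR-pTPP"},
    {"name": "ptpp_rate_fold_reduction", "kind": "fold", "quantity": "k",
     "a": "FFpSPR-Pin1", "b": "FFpSPR-pTPP"},
    {"name": "ww_addition_deff_fold", "kind": "fold", "quantity": "d_eff",
     "a": "FFpSPR-Pin1", "b": "FFpSPR-PPIase"},
    {"name": "ww_ligand_deff_fold_reduction", "kind": "fold", "quantity": "d_eff",
     "a": "FFpSPR-Pin1", "b": "FFpSPR-FFpSPR"},
    {"name": "ptpp_deff_fold_reduction", "kind": "fold", "quantity": "d_eff",
     "a": "FFpSPR-Pin1", "b": "FFpSPR-pTPP"},
]
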
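"""Compiled inner loop of the stochastic expression dynamics.

One call advances a single cell's regulatory state by one time step.  The
cell's genome is pre-compiled into flat arrays (see ``regulation.Cell``);
the caller supplies one uniform draw per (gene copy, assigned site) pair.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STAGE_NONE = -1


@njit(cache=True)
def expression_step_kernel(
    gene_type,      # int64[nG] regulator type of each gene
    gene_thresh,    # int64[nG]
    act,            # uint8[nG, 2] current activity per copy (copy 1 valid iff copies == 2)
    copies,         # uint8[nG]
    site_ptr,       # int64[nG+1] CSR pointer: sites assigned to gene g are site_ptr[g]:site_ptr[g+1]
    site_target,    # int64[nS]
    site_weight,    # int64[nS]
    half_saturation,  # float64; <= 0 selects the deterministic binding limit
    u,              # float64[>= n_draws] uniforms
    act_out,        # uint8[nG, 2] output buffer
):
    """Synchronous update of every gene copy; returns the number of uniform
    draws consumed.

    A site targeting type t is bound with probability A/(A + K) where A is
    the number of active copies of type t genome-wide; a gene copy switches
    on iff the summed weight of its bound sites reaches its threshold.
    """
    n_genes = gene_type.size
    active = np.zeros(5, np.int64)
    for g in range(n_genes):
        active[gene_type[g]] += act[g, 0]
        if copies[g] == 2:
            active[gene_type[g]] += act[g, 1]
    k = 0
    for g in range(n_genes):
        for c in range(copies[g]):
            s = 0
            for j in range(site_ptr[g], site_ptr[g + 1]):
                a = active[site_target[j]]
                if half_saturation <= 0.0:
                    bound = a > 0
                else:
                    bound = u[k] * (a + half_saturation) < a
                k += 1
                if bound:
                    s += site_weight[j]
            act_out[g, c] = 1 if s >= gene_thresh[g] else 0
        if copies[g] == 1:
            act_out[g, 1] = 0
    return k


@njit(cache=True)
def advance_kernel(gene_type, gene_thresh, act, copies, site_ptr, site_target,
                   site_weight, half_saturation, u, act_out, table):
    """Fused per-step update: expression step + core pattern + stage match.

    Returns (stage_row, absorbed): stage_row is the row of ``table`` whose
    signature matches the new core pattern (-1 for none), absorbed is 1 iff
    every gene copy is now inactive.
    """
    expression_step_kernel(gene_type, gene_thresh, act, copies, site_ptr,
                           site_target, site_weight, half_saturation, u, act_out)
    core = core_pattern_kernel(gene_type, act_out, copies)
    absorbed = 1
    for t in range(5):
        if core[t]:
            absorbed = 0
            break
    return match_stage_kernel(core, table), absorbed


@njit(cache=True)
def core_pattern_kernel(gene_type, act, copies):
    """5-bit core vector: type t is on iff any copy of a type-t gene is active."""
    core = np.zeros(5, np.uint8)
    for g in range(gene_type.size):
        if act[g, 0] == 1 or (copies[g] == 2 and act[g, 1] == 1):
            core[gene_type[g]] = 1
    return core


@njit(cache=True)
def match_stage_kernel(core, table):
    """Row index of ``table`` (4x5) equal to ``core``, or -1."""
    for r in range(table.shape[0]):
        ok = True
        for t in range(5):
            if table[r, t] != core[t]:
                ok = False
                break
        if ok:
            return r
    return STAGE_NONE
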
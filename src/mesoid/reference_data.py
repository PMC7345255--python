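"""Published per-window identification results bundled as example data.

These tables come from a published multiscale compression-test validation
campaign on in-silico specimens (2D plane stress with Q=16 mesoscopic
observation windows, solved with both the fixed-point and genetic solvers,
and 3D with Q=3 specimens).  They serve as ready-made inputs for the
robustification stage and for evaluation-count bookkeeping, independent of
any forward simulation.

Columns of the per-window arrays: delta [-], ell [um], kappa_bar [GPa],
mu_bar [GPa]; ``*_N_ITERS`` are the per-window iteration (fixed point) or
generation (genetic) counts.
"""

from __future__ import annotations

import numpy as np

# 2D plane-stress validation, fixed-point solver, Q=16 windows, Ns=500, nV=10
FP2D_WINDOWS = np.array([
    [0.306, 147.778, 13.222, 3.717],
    [0.500, 224.444, 11.333, 3.717],
    [0.417, 122.222, 12.278, 3.717],
    [0.417, 122.222, 12.278, 3.717],
    [0.444, 147.778, 12.278, 3.717],
    [0.417, 122.222, 12.278, 3.717],
    [0.361, 147.778, 12.278, 3.717],
    [0.361, 147.778, 12.278, 3.717],
    [0.444, 147.778, 12.278, 3.717],
    [0.333, 147.778, 12.278, 3.717],
    [0.333, 122.222, 12.278, 3.717],
    [0.389, 96.667, 12.278, 3.717],
    [0.389, 147.778, 12.278, 3.717],
    [0.389, 122.222, 12.278, 3.717],
    [0.389, 147.778, 12.278, 3.717],
    [0.361, 122.222, 12.278, 3.717],
])
FP2D_N_ITERS = np.array([3, 4, 3, 3, 3, 4, 4, 4, 3, 4, 4, 3, 4, 3, 4, 4])
FP2D_NS = 500
FP2D_NV = 10
FP2D_B_TRUE = (0.400, 125.000, 13.750, 3.587)
FP2D_B_OPT = (0.391, 135.328, 12.273, 3.717)

# same campaign solved with the genetic algorithm, nI=40, Ns=50
GA2D_WINDOWS = np.array([
    [0.361, 122.222, 16.056, 2.411],
    [0.333, 147.778, 9.444, 2.933],
    [0.417, 198.889, 13.222, 3.194],
    [0.333, 147.778, 13.222, 3.456],
    [0.444, 147.778, 11.333, 4.239],
    [0.417, 173.333, 12.278, 2.933],
    [0.278, 147.778, 10.389, 3.717],
    [0.278, 147.778, 12.278, 3.194],
    [0.389, 96.667, 14.167, 3.978],
    [0.333, 96.667, 11.333, 2.933],
    [0.278, 96.667, 15.111, 2.933],
    [0.417, 122.222, 12.278, 4.239],
    [0.472, 122.222, 14.167, 3.456],
    [0.389, 96.667, 12.278, 2.672],
    [0.361, 122.222, 14.167, 3.456],
    [0.444, 173.333, 9.444, 3.978],
])
GA2D_N_GENS = np.array([193, 202, 189, 197, 207, 201, 192, 199, 210, 205,
                        203, 198, 194, 208, 190, 208])
GA2D_NI = 40
GA2D_NS = 50

# 3D validation, fixed-point solver, Q=3 specimens, Ns=500, nV=10
FP3D_WINDOWS = np.array([
    [0.311, 65.556, 150.000, 64.722],
    [0.367, 88.889, 150.000, 64.722],
    [0.311, 81.111, 150.000, 64.722],
])
FP3D_N_ITERS = np.array([3, 4, 3])
FP3D_NS = 500
FP3D_NV = 10
FP3D_B_TRUE = (0.320, 80.000, 145.000, 67.300)
FP3D_B_OPT = (0.330, 77.271, 150.000, 64.722)
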
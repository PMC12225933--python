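"""Package-wide default parameters.

All lengths in the mechanics/synthetic-mesh modules are expressed in units of
the *initial epidermis thickness* (the natural length scale of the folding
problem: fold wavelength is proportional to the thickness of the folding
layer).  Image-phantom lengths are in voxels; indentation lengths in microns.

Every default that stands in for a quantity the source data does not pin down
lives here rather than in function signatures, so a user can see — and
override — the full set of modelling choices in one place.
"""

from __future__ import annotations

# --- synthetic layered cap (the "central dorsal head region" stand-in) -----
CAP_RADIUS = 150.0         # outer (epidermis) radius of the spherical cap;
                           # large relative to the skin thickness (6 units)
                           # as on a real skull, so frustrated tangential
                           # growth cannot escape into smooth radial
                           # inflation of the dome
CAP_H_EPIDERMIS = 1.0      # epidermis thickness == 1 length unit by definition
CAP_H_DERMIS = 5.0         # dermis thickness
CAP_H_BONE = 2.0           # meshed rigid bone shell thickness
CAP_HALF_WIDTH_FRACTION = 1.0 / 15.0   # lateral half-width of the patch as a
                                       # fraction of CAP_RADIUS: a 20x20-unit
                                       # patch hosting a handful of fold
                                       # wavelengths at desk-scale cost
CAP_RESOLUTION = 2         # element layers across the epidermis thickness
CAP_INPLANE_SPACING = 1.0  # target in-plane element size (epidermis units)
PERTURB_AMPLITUDE = 1e-3   # geometric symmetry-breaking RMS amplitude
PERTURB_CORRELATION = 2.0  # correlation length of the perturbation field
                           # (epidermis-thickness units); fluctuations are
                           # smooth at tissue scale, not grid-scale jitter
GROWTH_NOISE_AMPLITUDE = 0.10   # RMS of the multiplicative stochastic
                                # spatial fluctuation of the growth field;
                                # nucleates subcritical creases
GROWTH_NOISE_CORRELATION = 2.0  # its correlation length (epidermis units)

# --- image phantom ----------------------------------------------------------
PHANTOM_EPIDERMIS_INTENSITY = 0.8   # dense nuclear packing -> bright band
PHANTOM_DERMIS_INTENSITY = 0.25     # sparse nuclei -> dim band
PHANTOM_CELL_RADIUS = 3.0           # blob radius, voxels
PHANTOM_CELL_AMPLITUDE = 0.6        # peak added intensity of one labelled cell
PHANTOM_BONE_THICKNESS = 3.0        # bone shell thickness, voxels
PHANTOM_DOME_APEX_FRACTION = 0.75   # dome apex height as fraction of stack z

# --- segmentation -----------------------------------------------------------
CANNY_SIGMA = 1.5                 # Gaussian scale for edge detection, voxels
CANNY_LOW_QUANTILE = 0.10         # hysteresis thresholds as gradient-magnitude
CANNY_HIGH_QUANTILE = 0.40        # quantiles over surviving ridge voxels; low
                                  # enough that the dimmer epidermis-dermis
                                  # boundary seeds its own component
RECON_SPACING = 2.0               # implicit-surface grid spacing, voxels
RECON_NEIGHBORS = 10              # kNN used by the signed moving-least-squares field
CELL_DETECT_SCALE = 1.5           # Hessian smoothing scale ~= cell radius / 2
CELL_DETECT_THRESHOLD = 0.02      # min |smallest-magnitude principal curvature|;
                                  # sits between blob responses (~0.04 for unit-
                                  # amplitude nuclei) and layer-boundary responses

# --- growth mechanics -------------------------------------------------------
RAMP_STEPS = 50            # growth increments from 0 to the final values
DT_SAFETY = 0.5            # explicit-stability safety factor (alpha)
DAMPING_ZETA = 0.02        # viscous drag as a fraction of the stiffest
                           # element frequency (scale-invariant); kept light
                           # so buckling modes can develop during relaxation
CONTACT_RADIUS = 0.5       # self-contact detection radius, epidermis units
CONTACT_STIFFNESS = 5.0    # penalty stiffness relative to the stiffest modulus
CONTACT_REFRESH = 25       # steps between contact candidate-pair refreshes
CONTACT_EXCLUSION = 2.5    # reference-distance below which node/triangle pairs
                           # are considered neighbours, not contact
RESIDUAL_TOL = 2e-5        # convergence: max nodal force / (E_scale * unit^2)
MAX_STEPS_PER_INCREMENT = 1000
FINAL_RELAX_STEPS = 8000   # extra relaxation budget after the last increment

# --- pattern analysis -------------------------------------------------------
CREASE_QUANTILE = 0.10     # adaptive crease threshold: 10th curvature percentile
CREASE_FLOOR = 0.01        # |curvature| below this never counts as a crease
                           # (units: 1 / epidermis thickness); above the
                           # ripple left by the geometric symmetry-breaking
                           # jitter, below any real fold valley
CREASE_FIXED_THRESHOLD = -0.05  # fixed-mode crease threshold used when
                                # comparing different surfaces/species

# --- indentation ------------------------------------------------------------
PROBE_RADIUS_UM = 99.0     # spherical probe tip radius
MAX_DEPTH_UM = 2.0         # indentation depth
N_CURVE_SAMPLES = 100      # samples per load-displacement curve
FIT_QUALITY_MIN = 0.95     # Hertz-fit R^2 retention threshold (inclusive)
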
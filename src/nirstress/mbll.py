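"""Modified Beer-Lambert law (MBLL) conversion.

The optical-density change at wavelength lambda relates linearly to the
chromophore concentration changes:

    dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d * DPF(lambda)

with d the source-detector distance and DPF the differential pathlength
factor. With two wavelengths this is a 2x2 linear system per channel and
sample, solved in both directions (forward for simulation, inverse for
measured data).

Extinction coefficients are compiled from the Prahl/Cope-Delpy tabulations,
converted to 1/(uM*mm); with dHbO/dHbR in uM and d in mm, dOD is
dimensionless. The table is a module-level dict so alternative compilations
can be supplied. The laterality analysis is invariant to the absolute scale
of these constants.
"""

from __future__ import annotations

import numpy as np

from .containers import ChannelLayout, HemoTimeSeries, OpticalRecording

# eps[(wavelength_nm)] = (eps_HbO, eps_HbR) in 1/(uM*mm)
# (molar extinction in 1/(cm*M) x 1e-7)
EXTINCTION_UM_MM: dict[float, tuple[float, float]] = {
    690.0: (2.76e-05, 2.1382e-04),
    750.0: (5.18e-05, 1.4052e-04),
    780.0: (7.10e-05, 1.0754e-04),
    808.0: (8.60e-05, 7.84e-05),
    830.0: (9.74e-05, 6.93e-05),
    850.0: (1.058e-04, 6.91e-05),
}

DEFAULT_DPF = (6.0, 6.0)  # per wavelength; the device DPF is not published


def extinction_matrix(wavelengths_nm, table=None) -> np.ndarray:
    """Rows = wavelengths, columns = (HbO, HbR) extinction in 1/(uM*mm)."""
    table = EXTINCTION_UM_MM if table is None else table
    rows = []
    for wl in wavelengths_nm:
        if float(wl) not in table:
            raise ValueError(
                f"no extinction coefficients for {wl} nm; "
                f"known wavelengths: {sorted(table)}"
            )
        rows.append(table[float(wl)])
    return np.asarray(rows, dtype=float)


def _system_matrix(layout: ChannelLayout, dpf, table=None) -> np.ndarray:
    eps = extinction_matrix(layout.wavelengths_nm, table)
    dpf = np.asarray(dpf, dtype=float)
    if dpf.shape != (len(layout.wavelengths_nm),):
        raise ValueError("dpf must give one factor per wavelength")
    a = eps * (layout.source_detector_distance_mm * dpf[:, None])
    if np.linalg.matrix_rank(a) < 2:
        raise ValueError(
            f"singular extinction system for wavelengths {layout.wavelengths_nm}; "
            "two spectrally distinct wavelengths are required"
        )
    return a


def forward_mbll(
    hemo: HemoTimeSeries, layout: ChannelLayout, dpf=DEFAULT_DPF, table=None
) -> OpticalRecording:
    """Map concentration changes to optical-density changes (simulation direction)."""
    a = _system_matrix(layout, dpf, table)
    conc = np.stack([hemo.dhbo, hemo.dhbr], axis=1)  # channels x 2 x samples
    dod = np.einsum("wk,cks->cws", a, conc)
    return OpticalRecording(dod=dod, fs_hz=hemo.fs_hz, wavelengths_nm=layout.wavelengths_nm)


def mbll_inverse(
    rec: OpticalRecording, layout: ChannelLayout, dpf=DEFAULT_DPF, table=None
) -> HemoTimeSeries:
    """Solve the per-sample 2x2 MBLL system for (dHbO, dHbR)."""
    if len(rec.wavelengths_nm) < 2:
        raise ValueError("at least two wavelengths are required")
    a = _system_matrix(layout, dpf, table)
    a_inv = np.linalg.inv(a)
    conc = np.einsum("kw,cws->cks", a_inv, rec.dod)
    return HemoTimeSeries(dhbo=conc[:, 0, :], dhbr=conc[:, 1, :], fs_hz=rec.fs_hz)
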
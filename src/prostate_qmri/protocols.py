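"""Acquisition-protocol dialects of the two participating institutions.

Two scanning protocols are modelled.  Dialect "A" (UMCU-style) acquires DWI
with six b-values on a coarse voxel grid and no multi-echo T2 mapping series;
its ADC maps are fitted from b = 300, 500, 800 s/mm^2.  Dialect "B"
(NKI-style) acquires DWI with b = 0, 200, 800 s/mm^2 on a finer grid plus a
12-echo spin-echo series (first TE 32 ms, 16 ms spacing) from which T2 maps
are fitted; its ADC maps use b = 200 and 800 s/mm^2.  Only b-values in the
perfusion-insensitive 200-800 s/mm^2 range enter ADC fits in either dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProtocolDialect", "DIALECT_A", "DIALECT_B", "DIALECTS", "dwi_voxel_volume_ratio"]


@dataclass(frozen=True)
class ProtocolDialect:
    name: str
    dwi_b_values: tuple[float, ...]
    adc_b_subset: tuple[float, ...]
    dwi_acquired_voxel_mm: tuple[float, float, float]
    # single-shot EPI is zero-fill reconstructed to a finer grid; ADC maps
    # live on the reconstructed grid while SNR follows the acquired voxel
    dwi_recon_voxel_mm: tuple[float, float, float] = (1.1, 1.1, 3.0)
    has_t2_mapping: bool = False
    echo_times_ms: tuple[float, ...] = ()
    echo_acquired_voxel_mm: tuple[float, float, float] | None = None
    t2w_te_ms: float = 120.0
    t2w_voxel_mm: tuple[float, float, float] = (0.7, 0.7, 3.0)

    def dwi_voxel_volume(self) -> float:
        """Acquired DWI voxel volume in mm^3."""
        return float(np.prod(self.dwi_acquired_voxel_mm))


DIALECT_A = ProtocolDialect(
    name="A",
    dwi_b_values=(0.0, 100.0, 300.0, 500.0, 800.0, 1000.0),
    adc_b_subset=(300.0, 500.0, 800.0),
    dwi_acquired_voxel_mm=(3.0, 3.0, 4.0),
    dwi_recon_voxel_mm=(2.5, 2.5, 4.0),
    has_t2_mapping=False,
    t2w_te_ms=95.0,
    t2w_voxel_mm=(0.6, 0.7, 3.0),
)

# 12 echoes: TE = 32, 48, ..., 208 ms
DIALECT_B = ProtocolDialect(
    name="B",
    dwi_b_values=(0.0, 200.0, 800.0),
    adc_b_subset=(200.0, 800.0),
    dwi_acquired_voxel_mm=(2.3, 2.4, 3.0),
    dwi_recon_voxel_mm=(1.1, 1.1, 3.0),
    has_t2_mapping=True,
    echo_times_ms=tuple(32.0 + 16.0 * i for i in range(12)),
    echo_acquired_voxel_mm=(0.8, 0.8, 3.0),
    t2w_te_ms=120.0,
    t2w_voxel_mm=(0.7, 0.7, 3.0),
)

DIALECTS = {"A": DIALECT_A, "B": DIALECT_B}


def dwi_voxel_volume_ratio(
    a: ProtocolDialect = DIALECT_A, b: ProtocolDialect = DIALECT_B
) -> float:
    """Ratio of acquired DWI voxel volumes between two protocol dialects.

    With the default dialects this quantifies the SNR-relevant geometry gap
    between the coarse 3.0x3.0x4 mm and fine 2.3x2.4x3 mm DWI acquisitions.
    """
    return a.dwi_voxel_volume() / b.dwi_voxel_volume()
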
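"""Thornthwaite potential evapotranspiration and a single-bucket water balance.

These are the hydrologic primitives behind the "water availability"
covariate hypothesis: a monthly PET estimate driven only by temperature,
and a fixed-capacity soil-moisture bucket that partitions precipitation
into actual evapotranspiration, storage, deficit, and surplus (runoff).
No snow module, no routing, no calibration — the bucket is an auditable
surrogate for a macroscale hydrologic model.
"""

from __future__ import annotations

import numpy as np

__all__ = ["thornthwaite_pet", "bucket_water_balance"]


def thornthwaite_pet(temp: np.ndarray) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) from monthly mean temperature.

    Parameters
    ----------
    temp
        Array of monthly mean temperatures in °C whose last axis has length
        a multiple of 12 (consecutive Jan..Dec blocks).  The annual heat
        index is computed per 12-month block.

    Notes
    -----
    Classic Thornthwaite: ``PET = 16 * (10*T/I)**a`` for T > 0, else 0,
    with heat index ``I = sum((T/5)**1.514)`` over the year's months with
    T > 0 and ``a`` the standard cubic in I.  The day-length correction is
    taken as 1 (latitude-free), so values are comparable across synthetic
    sites rather than calibrated to a real place.
    """
    temp = np.asarray(temp, dtype=float)
    if temp.shape[-1] % 12 != 0:
        raise ValueError(f"last axis must be a multiple of 12 months, got {temp.shape[-1]}")
    shape = temp.shape[:-1] + (temp.shape[-1] // 12, 12)
    t = temp.reshape(shape)
    tpos = np.clip(t, 0.0, None)
    heat = np.sum((tpos / 5.0) ** 1.514, axis=-1, keepdims=True)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * tpos / heat) ** a
    pet = np.where((tpos <= 0.0) | (heat <= 0.0), 0.0, pet)
    return pet.reshape(temp.shape)


def bucket_water_balance(
    precip: np.ndarray,
    pet: np.ndarray,
    capacity: float = 150.0,
    initial_fraction: float = 0.5,
) -> dict[str, np.ndarray]:
    """Iterate the monthly soil-moisture bucket along the last axis.

    Each month the water available is last month's storage plus this
    month's precipitation; actual evapotranspiration removes up to PET
    from it; what remains refills the bucket up to ``capacity`` and any
    excess leaves as surplus (runoff).

    Returns a dict with ``storage`` (month-end, mm), ``aet`` (mm),
    ``deficit`` (PET − AET, mm) and ``surplus`` (mm), all shaped like the
    inputs.
    """
    if capacity < 0:
        raise ValueError(f"bucket capacity must be nonnegative, got {capacity}")
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if precip.shape != pet.shape:
        raise ValueError("precip and pet must have identical shapes")
    n = precip.shape[-1]
    storage = np.empty_like(precip)
    aet = np.empty_like(precip)
    surplus = np.empty_like(precip)
    prev = np.full(precip.shape[:-1], capacity * initial_fraction)
    for m in range(n):
        available = prev + precip[..., m]
        aet_m = np.minimum(pet[..., m], available)
        remaining = available - aet_m
        stored = np.minimum(remaining, capacity)
        surplus[..., m] = remaining - stored
        storage[..., m] = stored
        aet[..., m] = aet_m
        prev = stored
    return {
        "storage": storage,
        "aet": aet,
        "deficit": pet - aet,
        "surplus": surplus,
    }
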
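"""Shared construction helpers for the test suite."""
import numpy as np

from noncanon_pk.io import ConcProfile, ConcUnits, Tissue


def make_profile(times, concs, tissue=Tissue.BLOOD, units=ConcUnits.NG_PER_ML, group="g1"):
    return ConcProfile(
        group_id=group,
        tissue=tissue,
        times=np.asarray(times, float),
        concentrations=np.asarray(concs, float),
        units=units,
    )
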
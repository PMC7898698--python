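"""Shared fixtures: small synthetic geometries and profiles.

Everything is generated programmatically and seeded, so the suite needs
no data files.
"""

import numpy as np
import pytest
from shapely.geometry import Point, box

from myoxi import (Fibre, MuscleSection, SectionProfile,
                   study_mechanics_profiles, study_section_profiles)


@pytest.fixture
def small_profile():
    """A quick 40-fibre soleus-like section profile."""
    return SectionProfile(
        group_label="test", muscle="soleus", n_fibres=40,
        type_fractions={"I": 0.9, "IIa": 0.1},
        mean_fcsa={"I": 2000.0, "IIa": 1800.0},
        fcsa_cv=0.2, target_cf_ratio=2.0, roi_side=330.0, seed=11)


@pytest.fixture
def control_soleus_profile():
    return study_section_profiles(seed=5)["control_soleus"]


@pytest.fixture
def soleus_mechanics():
    return study_mechanics_profiles(seed=3)["control_soleus"]


@pytest.fixture
def krogh_section():
    """Disc tissue with one central capillary (Krogh-cylinder geometry)."""
    centre = (100.0, 100.0)
    roi = Point(*centre).buffer(99.999, quad_segs=64)
    fibre = Fibre(Point(*centre).buffer(99.99, quad_segs=64), "I")
    return MuscleSection(roi=roi, fibres=[fibre],
                         capillaries=np.array([centre]), meta={})


@pytest.fixture
def square_section():
    """100×100 µm ROI fully covered by one square fibre, 3 capillaries."""
    roi = box(0, 0, 100, 100)
    return MuscleSection(
        roi=roi, fibres=[Fibre(box(0, 0, 100, 100), "I")],
        capillaries=np.array([[25.0, 25.0], [75.0, 25.0], [50.0, 80.0]]),
        meta={})
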
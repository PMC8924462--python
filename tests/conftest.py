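from __future__ import annotations

import itertools

import pytest

from crcatlas.events import CellEvent, Panel, SizeClass

_counter = itertools.count()


def make_event(**kwargs) -> CellEvent:
    """Event factory with sane defaults; override any field via kwargs."""
    i = next(_counter)
    defaults = dict(
        patient_id="p1",
        sample_id="s1",
        disease_group="synthetic",
        event_id=f"e{i}",
        cep8_spots=3,
        cd45=False,
        pm=False,
        cd31=False,
        vim=False,
        cd133=False,
        panel=Panel.TUMOR,
        panel_marker_name="EpCAM",
        diameter_um=12.0,
    )
    defaults.update(kwargs)
    return CellEvent(**defaults)


@pytest.fixture
def event_factory():
    return make_event
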
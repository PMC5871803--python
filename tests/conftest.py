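import numpy as np
import pytest

MINIMAL_RSML = """<?xml version="1.0" encoding="UTF-8"?>
<rsml>
  <metadata>
    <version>1</version>
    <unit>cm</unit>
    <resolution>1</resolution>
  </metadata>
  <scene>
    <plant ID="plant1">
      <root ID="root1">
        <geometry><polyline>
          <point x="0" y="0"/>
          <point x="0" y="5"/>
        </polyline></geometry>
        <functions><function name="diameter" domain="polyline">
          <sample value="0.1"/><sample value="0.1"/>
        </function></functions>
      </root>
    </plant>
  </scene>
</rsml>
"""

NESTED_RSML = """<?xml version="1.0" encoding="UTF-8"?>
<rsml>
  <metadata><version>1</version><unit>mm</unit><resolution>2</resolution></metadata>
  <scene>
    <plant ID="p">
      <root ID="axis">
        <geometry><polyline>
          <point x="0" y="0"/><point x="0" y="2"/><point x="0" y="5"/>
        </polyline></geometry>
        <functions><function name="diameter" domain="polyline">
          <sample value="0.2"/><sample value="0.2"/><sample value="0.2"/>
        </function></functions>
        <root ID="lat1">
          <geometry><polyline>
            <point x="0" y="2"/><point x="1" y="2"/>
          </polyline></geometry>
          <functions><function name="diameter" domain="polyline">
            <sample value="0.1"/><sample value="0.1"/>
          </function></functions>
        </root>
        <root ID="lat2">
          <geometry><polyline>
            <point x="0" y="5"/><point x="-1" y="5"/>
          </polyline></geometry>
        </root>
      </root>
    </plant>
  </scene>
</rsml>
"""


@pytest.fixture
def minimal_rsml_text():
    return MINIMAL_RSML


@pytest.fixture
def nested_rsml_text():
    return NESTED_RSML


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
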
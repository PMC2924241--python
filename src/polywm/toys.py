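"""Hand-built toy networks.

The seven-neuron two-group toy: two anchor neurons plus five followers wired
through two separate synapse sets ("red" and "black") whose conduction
delays are arranged so that the same seven neurons support two distinct
polychronous groups.  Firing anchor A then anchor B 10 ms later ignites the
red follower order (2,3,4,5,6); the reverse anchor timing ignites the black
order (6,4,2,5,3).

Each follower needs two coincident arrivals to fire, and each group is a
feed-forward chain (anchor + previous follower converge on the next
follower), so partial or mixed ignitions die out instead of producing
spurious hybrid groups.  The delay values are one valid assignment — only
the two firing orders are constrained.
"""

from __future__ import annotations

import numpy as np

from .network import Network, NetworkConfig
from .neurons import RS
from .png import IGNITION_LAG, PNGTemplate, simulate_template

TOY_W = 12.0  # two coincident arrivals (24 mV) fire a follower; one does not

#: red chain: (postsynaptic, (pre_a, pre_b), firing time); anchors 0@0, 1@10
_RED = [(2, (0, 1), 15), (3, (1, 2), 19), (4, (2, 3), 23),
        (5, (3, 4), 27), (6, (4, 5), 31)]
#: black chain: anchors 1@0, 0@10
_BLACK = [(6, (1, 0), 15), (4, (0, 6), 19), (2, (6, 4), 23),
          (5, (4, 2), 27), (3, (2, 5), 31)]


def _chain_synapses(chain, anchor_times):
    """Delays so both arrivals land IGNITION_LAG ms before the firing time."""
    fire_at = dict(anchor_times)
    rows = []
    for post, pres, t in chain:
        for pre in pres:
            d = t - IGNITION_LAG - fire_at[pre]
            if not (1 <= d <= 20):  # pragma: no cover - static layout
                raise ValueError("toy delay out of range")
            rows.append((pre, post, d))
        fire_at[post] = t
    return rows


def two_group_toy() -> tuple[Network, PNGTemplate, PNGTemplate]:
    """Build the toy network and return it with the red and black templates."""
    config = NetworkConfig(
        n_neurons=7, excitatory_fraction=1.0, connection_prob=0.99,
        w_max=TOY_W, mini_rate=0.0, mini_amplitude=0.0,
        init_weight_mode="mature",
    )
    rows = _chain_synapses(_RED, {0: 0, 1: 10})
    rows += _chain_synapses(_BLACK, {1: 0, 0: 10})
    pre, post, delay = map(np.asarray, zip(*rows))
    m = len(pre)
    n = 7
    net = Network(
        config=config, seed=0, exc=np.ones(n, dtype=bool),
        a=np.full(n, RS.a), b=np.full(n, RS.b),
        c=np.full(n, RS.c), d=np.full(n, RS.d),
        pre=pre.astype(np.int32), post=post.astype(np.int32),
        delay=delay.astype(np.int16), weight=np.full(m, TOY_W),
        plastic=np.ones(m, dtype=bool),
    )
    red = simulate_template(net, [(0, 0.0), (1, 10.0)], min_size=7)
    black = simulate_template(net, [(1, 0.0), (0, 10.0)], min_size=7)
    if red is None or black is None:  # pragma: no cover
        raise RuntimeError("toy wiring failed to ignite")
    red.id, black.id = 0, 1
    return net, red, black


def follower_order(template: PNGTemplate, anchors=(0, 1)) -> list[int]:
    """Follower neurons of a toy template in firing order."""
    pairs = [(t, int(n)) for n, t in zip(template.neurons, template.times)
             if int(n) not in anchors]
    return [n for _, n in sorted(pairs)]
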
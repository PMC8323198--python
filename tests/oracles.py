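"""Naive per-pixel reference implementations used as independent oracles.

Each function mirrors its loss/metric definition with explicit Python loops
over pixels, deliberately avoiding the vectorized code paths under test.
"""

import math

import numpy as np

EPS = 1e-5
CLIP = 1e-7

REGION_MEMBERS = {
    "background": (0,),
    "complete": (1, 2, 3, 4),
    "core": (1, 3, 4),
    "enhancing": (4,),
}


def _pixels(P):
    return P.reshape(-1, P.shape[-1])


def naive_cross_entropy(P, G):
    P, G = _pixels(np.asarray(P, float)), _pixels(np.asarray(G, float))
    total = 0.0
    for i in range(len(P)):
        for k in range(P.shape[1]):
            p = min(max(P[i, k], CLIP), 1.0 - CLIP)
            total += G[i, k] * math.log(p)
    return -total / len(P)


def _naive_dice(p_vals, g_vals):
    num = sum(p * g for p, g in zip(p_vals, g_vals))
    den = sum(p_vals) + sum(g_vals)
    return 1.0 - (2.0 * num + EPS) / (den + EPS)


def naive_dice_class(P, G, k):
    P, G = _pixels(np.asarray(P, float)), _pixels(np.asarray(G, float))
    return _naive_dice([P[i, k] for i in range(len(P))], [G[i, k] for i in range(len(G))])


def naive_dice_region(P, G, region):
    P, G = _pixels(np.asarray(P, float)), _pixels(np.asarray(G, float))
    members = REGION_MEMBERS[region]
    p_vals = [sum(P[i, k] for k in members) for i in range(len(P))]
    g_vals = [sum(G[i, k] for k in members) for i in range(len(G))]
    return _naive_dice(p_vals, g_vals)


def naive_combined_dice(P, G):
    return sum(naive_dice_region(P, G, r) for r in ("background", "complete", "core", "enhancing"))


def naive_sliced_dice(P, G):
    return sum(naive_dice_class(P, G, k) for k in range(5))


def naive_recall(P, G, target):
    P, G = _pixels(np.asarray(P, float)), _pixels(np.asarray(G, float))
    members = (target,) if isinstance(target, int) else REGION_MEMBERS[target]
    num = 0.0
    den = 0.0
    for i in range(len(P)):
        p = sum(P[i, k] for k in members)
        g = sum(G[i, k] for k in members)
        num += p * g
        den += g
    return 1.0 - (num + EPS) / (den + EPS)


def naive_hl1(P, G, alpha=20.0, beta=0.5, gamma=1.0, delta=0.5):
    return (alpha * naive_cross_entropy(P, G)
            + beta * naive_recall(P, G, "complete")
            + gamma * naive_recall(P, G, "core")
            + delta * naive_recall(P, G, "enhancing"))


def naive_hl2(P, G, alpha=1.0, beta=0.1, gamma=1.3, delta=0.5):
    return (alpha * naive_combined_dice(P, G)
            + beta * naive_recall(P, G, "complete")
            + gamma * naive_recall(P, G, "core")
            + delta * naive_recall(P, G, "enhancing"))


def naive_mask_counts(P, G):
    """Brute-force |P|, |G|, |P n G| by iterating every voxel."""
    P = np.asarray(P).astype(bool).reshape(-1)
    G = np.asarray(G).astype(bool).reshape(-1)
    n_p = n_g = n_i = 0
    for a, b in zip(P, G):
        n_p += a
        n_g += b
        n_i += a and b
    return n_p, n_g, n_i


def naive_msffn_param_count(stage_channels=(16, 32, 64, 128, 256),
                            stage_units=(4, 2, 2, 2, 2),
                            fusing_channels=64, in_channels=4, num_classes=5):
    """Layer-by-layer arithmetic for the default architecture's parameter total.

    conv 3x3 with bias: 9*cin*cout + cout; BN: 4 per channel (scale, shift,
    moving mean, moving variance); classifier 1x1: cin*cout + cout.
    """
    total = 0
    cin = in_channels
    for c, units in zip(stage_channels, stage_units):
        for _ in range(units):
            total += 9 * cin * c + c      # conv kernel + bias
            total += 4 * c                # BN
            cin = c
    concat = stage_units[0] * stage_channels[0] + sum(stage_channels[1:])
    cin = concat
    for _ in range(3):
        total += 9 * cin * fusing_channels + fusing_channels
        total += 4 * fusing_channels
        cin = fusing_channels
    total += fusing_channels * num_classes + num_classes  # 1x1 classifier
    return total
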
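"""Shared finite-difference gradient-check utilities."""

import numpy as np


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_layer_gradients(layer, x, rtol=1e-5, atol=1e-7, train=True, rng=None):
    """Verify backward() against finite differences for input and parameters.

    Uses the scalar objective sum(w * forward(x)) with fixed random w.
    """
    rng = rng or np.random.default_rng(0)
    y = layer.forward(x, train=train)
    w = rng.standard_normal(y.shape)

    def objective():
        return float(np.sum(w * layer.forward(x, train=train)))

    for p in layer.params():
        p.grad[...] = 0.0
    layer.forward(x, train=train)
    dx = layer.backward(w.astype(x.dtype))

    dx_num = numeric_grad(objective, x)
    np.testing.assert_allclose(dx, dx_num, rtol=rtol, atol=atol)
    for p in layer.params():
        g_num = numeric_grad(objective, p.data)
        np.testing.assert_allclose(p.grad, g_num, rtol=rtol, atol=atol)
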
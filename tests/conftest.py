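"""Shared fixtures: published parameter sets and miniature circuits."""

import numpy as np
import pytest

from ca3net.network_builder import (
    BackgroundCurrentSpec,
    ConnectionSpec,
    IzhikevichParams,
    NetworkConfig,
    NeuronTypeSpec,
    TMSynapseParams,
    build_network,
    builtin_config_path,
    load_config,
)

#: Izhikevich parameters of the eight CA3 neuron types
#: (k, a, b, d, C, vr, vt, vmin, vpeak)
IZH_TABLE = {
    "Pyramidal": (1.54, 0.008, -35.78, 235, 102, -63.12, -23.96, -38.70, 36.40),
    "Axo-Axonic": (3.961, 0.005, 8.684, 15, 165, -57.100, -51.719, -73.969, 27.799),
    "Basket": (0.995, 0.004, 9.264, -6, 45, -57.506, -23.379, -47.556, 18.455),
    "Basket CCK+": (0.583, 0.006, -1.245, 54, 135, -58.997, -39.398, -42.771, 18.275),
    "Bistratified": (3.935, 0.002, 16.580, 19, 107, -64.673, -58.744, -59.703, -9.929),
    "Ivy": (1.916, 0.009, 1.908, 45, 364, -70.435, -40.859, -53.400, -6.920),
    "MFA-ORDEN": (1.380, 0.008, 12.933, 0, 209, -57.076, -39.102, -40.681, 16.313),
    "QuadD-LM": (1.776, 0.006, -3.449, 52, 186, -73.482, -54.937, -64.404, 7.066),
}


def izh_params(name: str) -> IzhikevichParams:
    k, a, b, d, C, vr, vt, vmin, vpeak = IZH_TABLE[name]
    return IzhikevichParams(C=C, k=k, vr=vr, vt=vt, a=a, b=b, d=d,
                            vpeak=vpeak, vmin=vmin)


@pytest.fixture(scope="session")
def pc_params() -> IzhikevichParams:
    return izh_params("Pyramidal")


@pytest.fixture(scope="session")
def pcpc_tm() -> TMSynapseParams:
    # pyramidal -> pyramidal unitary synapse
    return TMSynapseParams(g=0.55, tau_d=7.55, tau_r=318.51, tau_f=21.45, U=0.27)


@pytest.fixture(scope="session")
def full_config() -> NetworkConfig:
    return load_config(builtin_config_path("full_scale"))


def make_tiny_config(
    n_pc: int = 60,
    n_basket: int = 20,
    c_pcpc: float = 0.3,
    c_pc_bc: float = 0.2,
    c_bc_pc: float = 0.2,
    tm_g_scale: float = 1.0,
    pc_mu: float = 4.0,
    pc_sigma2: float = 1.5,
) -> NetworkConfig:
    """A two-type miniature circuit for fast protocol/engine tests."""
    pc = NeuronTypeSpec(
        name="Pyramidal", count=n_pc, izh=izh_params("Pyramidal"),
        background=BackgroundCurrentSpec(mu=pc_mu, sigma2=pc_sigma2,
                                         mu_presentation=pc_mu,
                                         sigma2_presentation=1.0),
        is_excitatory=True,
    )
    bc = NeuronTypeSpec(
        name="Basket", count=n_basket, izh=izh_params("Basket"),
        background=BackgroundCurrentSpec(mu=5.5, sigma2=1.0),
    )
    tm_pcpc = TMSynapseParams(g=0.55 * tm_g_scale, tau_d=7.55, tau_r=318.51,
                              tau_f=21.45, U=0.27)
    tm_pcbc = TMSynapseParams(g=0.88 * tm_g_scale, tau_d=3.97, tau_r=691.42,
                              tau_f=21.16, U=0.22)
    tm_bcpc = TMSynapseParams(g=1.18 * tm_g_scale, tau_d=7.64, tau_r=384.34,
                              tau_f=16.74, U=0.23)
    conns = {
        ("Pyramidal", "Pyramidal"): ConnectionSpec(
            "Pyramidal", "Pyramidal", probability=c_pcpc, tm=tm_pcpc, plastic=True),
        ("Pyramidal", "Basket"): ConnectionSpec(
            "Pyramidal", "Basket", probability=c_pc_bc, tm=tm_pcbc),
        ("Basket", "Pyramidal"): ConnectionSpec(
            "Basket", "Pyramidal", probability=c_bc_pc, tm=tm_bcpc),
    }
    return NetworkConfig(neuron_types={"Pyramidal": pc, "Basket": bc},
                         connections=conns)


@pytest.fixture()
def tiny_config() -> NetworkConfig:
    return make_tiny_config()


@pytest.fixture()
def tiny_network(tiny_config):
    return build_network(tiny_config, assembly_size=10, n_assemblies=2,
                         overlap_fraction=0.0, seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240327)
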
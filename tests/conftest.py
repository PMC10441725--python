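import pytest

from oncocea import builtin_inputs


@pytest.fixture(scope="session")
def overall_inputs():
    return builtin_inputs("overall")


@pytest.fixture(scope="session")
def brca_inputs():
    return builtin_inputs("brca_mut")


@pytest.fixture(scope="session")
def hrd_inputs():
    return builtin_inputs("hrd_pos")
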
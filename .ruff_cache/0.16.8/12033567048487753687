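/root/pkg/teststest_units.pytest_analysis.pytest_cli.pytest_md.pytest_fem.pytest_material.pytest_coupling.pytest_spatula.pytest_fixtures.pyconftest.pytest_acceptance.pytest_geometry.py�   ������O��䶝;��         �   ����^A���ӭ��;��         �   ����m��_,��;��         �   c���
�k�|T���;��         �   4�����~ 1����;��         �   �����y@֕��;��         �   ����<��Օ����;��         �   �����@�B��Ŷ�;��         �   ���tU4��*U���;��         �   T������p�5�ֶ�;��                                         �   ���fwT}�݀��;��         �   ����Uȃ�A����;��          V�V^VSyV�V^VSy����� �   ��������      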
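/root/pkg/src/setascalespatula.pygeometry.pymaterial.pyfixtures.pycoupling.py__init__.pyanalysis.py     cli.py����-w�9s�;��         �   ����ޯ������;��         �   �����B��Txz�;��         fem.py��"	�V%���;��         units.py]�xD��@��;��         �   :���u��c>��;��                                         �   ����c���n|�;��         �   ������ث�1:�;��         �   ����r_x��n�!�;��         �   o�����#��L�;��         md.py���Zl[�(O��;��         8Rbg�vP7o:8Rbg�vP7o:������� �   ��������      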
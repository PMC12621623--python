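/root/pkg/src/setascaleanalysis.pyspatula.pygeometry.pymaterial.pyfixtures.pycoupling.py__init__.py     �   �����B��Txz��;��         cli.py����-w�9s��;��         fem.py��"	�V%����;��         md.py���Zl[�(OӶ�;��         units.py]�xD��@���;��         �   E���u��c>���;��                                         �   ����Wk��7��;��          �   ������ث�1:��;��         �   �����Hn>�}$��;��          �   z���2�\���Ҷ�;��          �   O���ޯ�������;��         o8Rbg�vP:7o8Rbg�vP:7������� �   ��������      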